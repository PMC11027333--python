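"""Declarative biopsy-selection pathways over (PI-RADS, PSAD band).

A pathway is an ordered list of rules, each matching a set of PI-RADS scores
and a set of PSAD bands and yielding a biopsy / no-biopsy decision; the
first matching rule wins and a mandatory default makes the decision total.
Four built-in pathways are provided:

``biopsy_all``
    every man is biopsied, irrespective of MRI or PSAD.
``mri_focused``
    biopsy iff PI-RADS ≥ 3 (PSAD not considered).
``risk_low``
    low-threshold risk-adapted rule: PI-RADS 1–2 biopsied only in the very
    high PSAD band (≥0.20), PI-RADS 3 biopsied from the intermediate band
    up (≥0.10), PI-RADS 4–5 always.
``risk_high``
    high-threshold rule: PI-RADS 3 biopsied only in the very high band,
    PI-RADS 4–5 always, PI-RADS 1–2 never.

User-defined pathways can be loaded from YAML/JSON documents via
:func:`parse_pathway_config`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

import yaml

from .cohort import Cohort, PatientRecord, PsadBand, assign_psad_band
from .errors import ConfigError, ValidationError

__all__ = [
    "Decision",
    "PathwayRule",
    "PathwayDefinition",
    "DecisionSet",
    "BUILTIN_PATHWAY_NAMES",
    "builtin_pathways",
    "get_builtin_pathway",
    "decide_biopsy",
    "apply_pathway",
    "parse_pathway_config",
    "pathway_to_config",
]

ALL_PIRADS = frozenset({1, 2, 3, 4, 5})
ALL_BANDS = frozenset(PsadBand)


class Decision(Enum):
    BIOPSY = "biopsy"
    NO_BIOPSY = "no_biopsy"


@dataclass(frozen=True)
class PathwayRule:
    """Match on PI-RADS × band subsets; first matching rule wins."""

    pirads: frozenset
    bands: frozenset
    decision: Decision

    def __post_init__(self) -> None:
        if not self.pirads or not self.pirads <= ALL_PIRADS:
            raise ValidationError(f"rule pirads set must be a non-empty subset of 1..5, got {set(self.pirads)}")
        if not self.bands or not self.bands <= ALL_BANDS:
            raise ValidationError("rule band set must be a non-empty subset of the PSAD bands")

    def matches(self, pirads: int, band: PsadBand) -> bool:
        return pirads in self.pirads and band in self.bands


@dataclass(frozen=True)
class PathwayDefinition:
    """Named, total decision rule over the 5×4 (PI-RADS, band) grid."""

    name: str
    rules: tuple
    default_decision: Optional[Decision] = Decision.NO_BIOPSY

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("pathway name must be non-empty")
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.default_decision is None:
            uncovered = [
                (p, band.label)
                for p in sorted(ALL_PIRADS)
                for band in PsadBand
                if not any(r.matches(p, band) for r in self.rules)
            ]
            if uncovered:
                raise ValidationError(
                    f"pathway {self.name!r} has no default and leaves cells uncovered: {uncovered[:4]}"
                )

    def decide(self, pirads: int, band: PsadBand) -> Decision:
        for rule in self.rules:
            if rule.matches(pirads, band):
                return rule.decision
        assert self.default_decision is not None
        return self.default_decision


def _rule(pirads: Iterable[int], bands: Iterable[PsadBand], decision: Decision) -> PathwayRule:
    return PathwayRule(pirads=frozenset(pirads), bands=frozenset(bands), decision=decision)


def _builtins() -> tuple[PathwayDefinition, ...]:
    biopsy_all = PathwayDefinition(
        name="biopsy_all", rules=(), default_decision=Decision.BIOPSY
    )
    mri_focused = PathwayDefinition(
        name="mri_focused",
        rules=(_rule({3, 4, 5}, ALL_BANDS, Decision.BIOPSY),),
        default_decision=Decision.NO_BIOPSY,
    )
    risk_low = PathwayDefinition(
        name="risk_low",
        rules=(
            _rule({1, 2}, {PsadBand.VERY_HIGH}, Decision.BIOPSY),
            _rule({3}, {PsadBand.INTERMEDIATE, PsadBand.HIGH, PsadBand.VERY_HIGH}, Decision.BIOPSY),
            _rule({4, 5}, ALL_BANDS, Decision.BIOPSY),
        ),
        default_decision=Decision.NO_BIOPSY,
    )
    risk_high = PathwayDefinition(
        name="risk_high",
        rules=(
            _rule({3}, {PsadBand.VERY_HIGH}, Decision.BIOPSY),
            _rule({4, 5}, ALL_BANDS, Decision.BIOPSY),
        ),
        default_decision=Decision.NO_BIOPSY,
    )
    return (biopsy_all, mri_focused, risk_low, risk_high)


BUILTIN_PATHWAY_NAMES = ("biopsy_all", "mri_focused", "risk_low", "risk_high")


def builtin_pathways() -> tuple[PathwayDefinition, ...]:
    """The four built-in pathways, in comparator-first order."""
    return _builtins()


def get_builtin_pathway(name: str) -> PathwayDefinition:
    for p in _builtins():
        if p.name == name:
            return p
    raise ConfigError(f"unknown builtin pathway {name!r}; choose from {BUILTIN_PATHWAY_NAMES}")


def decide_biopsy(definition: PathwayDefinition, record: PatientRecord) -> Decision:
    """Apply a pathway to one patient (deterministic, first-match semantics)."""
    return definition.decide(record.pirads, assign_psad_band(record.psad))


@dataclass(frozen=True)
class DecisionSet:
    """Per-patient decisions of one pathway over one cohort."""

    pathway: str
    decisions: Mapping  # patient_id -> Decision

    def biopsied_ids(self) -> frozenset:
        return frozenset(pid for pid, d in self.decisions.items() if d is Decision.BIOPSY)

    def n_biopsy(self) -> int:
        return sum(1 for d in self.decisions.values() if d is Decision.BIOPSY)


def apply_pathway(definition: PathwayDefinition, cohort: Cohort) -> DecisionSet:
    """One decision per patient; pure function of (definition, cohort)."""
    if len(cohort) == 0:
        raise ValidationError("cannot apply a pathway to an empty cohort")
    return DecisionSet(
        pathway=definition.name,
        decisions={r.patient_id: decide_biopsy(definition, r) for r in cohort},
    )


# --------------------------------------------------------------------------
# Config documents
# --------------------------------------------------------------------------

_BAND_BY_NAME = {b.label: b for b in PsadBand}
_DECISIONS = {"biopsy": Decision.BIOPSY, "no_biopsy": Decision.NO_BIOPSY}


def parse_pathway_config(text: str) -> PathwayDefinition:
    """Parse a YAML (or JSON) pathway document into a validated definition.

    Schema::

        name: my_pathway
        default: no_biopsy          # optional iff rules cover all 20 cells
        rules:
          - pirads: [4, 5]          # required, subset of 1..5
            bands: [high, very_high]  # optional, default: all bands
            decision: biopsy        # required

    Errors carry the path to the offending key.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed document: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError("top level: expected a mapping")
    name = doc.get("name")
    if not isinstance(name, str) or not name:
        raise ConfigError("key 'name': expected a non-empty string")

    default = None
    if "default" in doc and doc["default"] is not None:
        default = _parse_decision(doc["default"], "default")

    rules_doc = doc.get("rules", [])
    if not isinstance(rules_doc, list):
        raise ConfigError("key 'rules': expected a list")
    rules = []
    for i, rd in enumerate(rules_doc):
        where = f"rules[{i}]"
        if not isinstance(rd, Mapping):
            raise ConfigError(f"{where}: expected a mapping")
        pirads_doc = rd.get("pirads")
        if not isinstance(pirads_doc, list) or not pirads_doc:
            raise ConfigError(f"{where}.pirads: expected a non-empty list of scores")
        pirads = set()
        for v in pirads_doc:
            if not isinstance(v, int) or v not in ALL_PIRADS:
                raise ConfigError(f"{where}.pirads: invalid PI-RADS value {v!r} (must be 1..5)")
            pirads.add(v)
        bands_doc = rd.get("bands")
        if bands_doc is None:
            bands = set(ALL_BANDS)
        else:
            if not isinstance(bands_doc, list) or not bands_doc:
                raise ConfigError(f"{where}.bands: expected a non-empty list of band names")
            bands = set()
            for v in bands_doc:
                if v not in _BAND_BY_NAME:
                    raise ConfigError(
                        f"{where}.bands: unknown band {v!r} "
                        f"(expected one of {sorted(_BAND_BY_NAME)})"
                    )
                bands.add(_BAND_BY_NAME[v])
        decision = _parse_decision(rd.get("decision"), f"{where}.decision")
        rules.append(PathwayRule(pirads=frozenset(pirads), bands=frozenset(bands), decision=decision))

    try:
        return PathwayDefinition(name=name, rules=tuple(rules), default_decision=default)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _parse_decision(value, where: str) -> Decision:
    if value not in _DECISIONS:
        raise ConfigError(f"key {where!r}: expected 'biopsy' or 'no_biopsy', got {value!r}")
    return _DECISIONS[value]


def pathway_to_config(definition: PathwayDefinition) -> dict:
    """Serialize a definition to the document form (round-trips via parse)."""
    doc: dict = {
        "name": definition.name,
        "rules": [
            {
                "pirads": sorted(r.pirads),
                "bands": [b.label for b in sorted(r.bands)],
                "decision": r.decision.value,
            }
            for r in definition.rules
        ],
    }
    if definition.default_decision is not None:
        doc["default"] = definition.default_decision.value
    return doc
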