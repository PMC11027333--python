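"""Cohort-level outcome metrics for biopsy pathways.

Three views of a cohort:

* :func:`cross_tabulate` — csPCa prevalence per (PI-RADS group, PSAD band)
  cell, PI-RADS grouped as 1–2 (negative MRI), 3 (equivocal), 4–5 (positive).
* :func:`pathway_outcomes` — detection / miss / avoidance counts of one
  pathway, all rates over the whole cohort N (the conventional denominator
  for pathway comparisons), with per-biopsy rates as secondary accessors.
* :func:`compare_chi_square` — Pearson chi-square on a 2×2 table comparing
  one outcome count between two pathways on the same cohort.

Two false-positive-style columns are reported because "negative biopsy" is
ambiguous: ``negative_biopsies`` counts biopsies finding no cancer of any
grade (benign only), while ``fp_non_cspca`` counts biopsies that do not find
clinically significant cancer (benign + iPCa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import Cohort, DiseaseStatus, PsadBand, disease_status
from .errors import ValidationError
from .pathways import Decision, DecisionSet, PathwayDefinition, apply_pathway

__all__ = [
    "PIRADS_GROUP_LABELS",
    "pirads_group",
    "CrossTab",
    "cross_tabulate",
    "OutcomeSummary",
    "pathway_outcomes",
    "outcome_table",
    "ChiSquareResult",
    "compare_chi_square",
    "COMPARABLE_METRICS",
]

PIRADS_GROUP_LABELS = ("1-2", "3", "4-5")


def pirads_group(pirads: int) -> str:
    """Aggregate PI-RADS score into the 1-2 / 3 / 4-5 reporting groups."""
    if pirads in (1, 2):
        return "1-2"
    if pirads == 3:
        return "3"
    if pirads in (4, 5):
        return "4-5"
    raise ValidationError(f"pirads must be 1..5, got {pirads!r}")


@dataclass(frozen=True)
class CrossTab:
    """Patient and csPCa counts per (PI-RADS group, PSAD band) cell.

    ``n`` and ``n_cspca`` are 3×4 integer arrays; rows follow
    :data:`PIRADS_GROUP_LABELS`, columns follow :class:`PsadBand` order.
    """

    n: np.ndarray
    n_cspca: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=int)
        c = np.asarray(self.n_cspca, dtype=int)
        if n.shape != (3, 4) or c.shape != (3, 4):
            raise ValidationError("cross-tab arrays must be 3x4")
        if (c > n).any() or (n < 0).any() or (c < 0).any():
            raise ValidationError("cell csPCa counts must satisfy 0 <= n_cspca <= n")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "n_cspca", c)

    def cell(self, group: str, band: PsadBand) -> tuple[int, int]:
        i = PIRADS_GROUP_LABELS.index(group)
        return int(self.n[i, band]), int(self.n_cspca[i, band])

    def prevalence(self, group: str, band: PsadBand) -> float:
        n, c = self.cell(group, band)
        if n == 0:
            raise ValidationError(f"empty cell ({group}, {band.label}) has no prevalence")
        return c / n

    @property
    def row_totals(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.n.sum())

    @property
    def total_cspca(self) -> int:
        return int(self.n_cspca.sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Cells as 'cspca/n' strings in the familiar report layout."""
        cols = [b.label for b in PsadBand]
        data = [
            [f"{self.n_cspca[i, j]}/{self.n[i, j]}" for j in range(4)]
            for i in range(3)
        ]
        return pd.DataFrame(data, index=list(PIRADS_GROUP_LABELS), columns=cols)


def cross_tabulate(cohort: Cohort) -> CrossTab:
    """Count patients and csPCa per (PI-RADS group, PSAD band) cell."""
    n = np.zeros((3, 4), dtype=int)
    c = np.zeros((3, 4), dtype=int)
    for r in cohort:
        i = PIRADS_GROUP_LABELS.index(pirads_group(r.pirads))
        j = int(r.psad_band)
        n[i, j] += 1
        if disease_status(r) is DiseaseStatus.CSPCA:
            c[i, j] += 1
    return CrossTab(n=n, n_cspca=c)


@dataclass(frozen=True)
class OutcomeSummary:
    """One pathway's detection / miss / avoidance accounting on a cohort.

    All ``*_rate`` properties use ``n_total`` as denominator.
    """

    pathway: str
    n_total: int
    n_biopsied: int
    n_avoided: int
    cspca_detected: int
    cspca_missed: int
    ipca_detected: int
    ipca_avoided: int
    negative_biopsies: int  # biopsied, no cancer of any grade
    fp_non_cspca: int  # biopsied, no csPCa (= negative_biopsies + ipca_detected)

    def __post_init__(self) -> None:
        checks = (
            self.n_biopsied + self.n_avoided == self.n_total,
            self.fp_non_cspca == self.negative_biopsies + self.ipca_detected,
            self.n_biopsied == self.cspca_detected + self.fp_non_cspca,
        )
        if not all(checks):
            raise ValidationError(f"inconsistent outcome counts for pathway {self.pathway!r}")

    def rate(self, count: int) -> float:
        return count / self.n_total

    @property
    def avoidance_rate(self) -> float:
        return self.rate(self.n_avoided)

    @property
    def cspca_detection_rate(self) -> float:
        return self.rate(self.cspca_detected)

    @property
    def cspca_missed_rate(self) -> float:
        return self.rate(self.cspca_missed)

    @property
    def ipca_detection_rate(self) -> float:
        return self.rate(self.ipca_detected)

    @property
    def negative_biopsy_rate(self) -> float:
        return self.rate(self.negative_biopsies)

    # Secondary, per-biopsy denominators
    @property
    def cspca_yield_per_biopsy(self) -> float:
        return self.cspca_detected / self.n_biopsied if self.n_biopsied else float("nan")

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "n_total": self.n_total,
            "n_biopsied": self.n_biopsied,
            "n_avoided": self.n_avoided,
            "cspca_detected": self.cspca_detected,
            "cspca_missed": self.cspca_missed,
            "ipca_detected": self.ipca_detected,
            "ipca_avoided": self.ipca_avoided,
            "negative_biopsies": self.negative_biopsies,
            "fp_non_cspca": self.fp_non_cspca,
            "avoidance_rate": self.avoidance_rate,
            "cspca_detection_rate": self.cspca_detection_rate,
            "cspca_missed_rate": self.cspca_missed_rate,
            "ipca_detection_rate": self.ipca_detection_rate,
        }


def pathway_outcomes(cohort: Cohort, decisions: DecisionSet) -> OutcomeSummary:
    """Intersect a decision set with ground truth to build one outcome row."""
    ids = set(cohort.ids())
    if set(decisions.decisions) != ids:
        raise ValidationError(
            f"decision set for pathway {decisions.pathway!r} does not cover the cohort "
            f"({len(decisions.decisions)} decisions vs {len(ids)} patients)"
        )
    n_biopsied = cspca_det = cspca_miss = ipca_det = ipca_avoid = neg_bx = 0
    for r in cohort:
        status = disease_status(r)
        selected = decisions.decisions[r.patient_id] is Decision.BIOPSY
        if selected:
            n_biopsied += 1
            if status is DiseaseStatus.CSPCA:
                cspca_det += 1
            elif status is DiseaseStatus.IPCA:
                ipca_det += 1
            else:
                neg_bx += 1
        else:
            if status is DiseaseStatus.CSPCA:
                cspca_miss += 1
            elif status is DiseaseStatus.IPCA:
                ipca_avoid += 1
    n = len(cohort)
    return OutcomeSummary(
        pathway=decisions.pathway,
        n_total=n,
        n_biopsied=n_biopsied,
        n_avoided=n - n_biopsied,
        cspca_detected=cspca_det,
        cspca_missed=cspca_miss,
        ipca_detected=ipca_det,
        ipca_avoided=ipca_avoid,
        negative_biopsies=neg_bx,
        fp_non_cspca=neg_bx + ipca_det,
    )


def outcome_table(cohort: Cohort, definitions: Sequence[PathwayDefinition]) -> list[OutcomeSummary]:
    """One outcome row per pathway, preserving input order."""
    if not definitions:
        raise ValidationError("outcome_table requires at least one pathway definition")
    return [pathway_outcomes(cohort, apply_pathway(d, cohort)) for d in definitions]


COMPARABLE_METRICS = (
    "cspca_detected",
    "ipca_detected",
    "cspca_missed",
    "n_avoided",
    "negative_biopsies",
    "fp_non_cspca",
)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    table: np.ndarray


def compare_chi_square(
    a: OutcomeSummary,
    b: OutcomeSummary,
    metric: str,
    *,
    correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square (df=1) comparing one count between two pathways.

    Builds the 2×2 table ``[[count_a, n−count_a], [count_b, n−count_b]]``;
    no Yates continuity correction by default.
    """
    if metric not in COMPARABLE_METRICS:
        raise ValidationError(f"metric must be one of {COMPARABLE_METRICS}, got {metric!r}")
    if a.n_total != b.n_total:
        raise ValidationError("pathways must be evaluated on cohorts of the same size")
    ca, cb = getattr(a, metric), getattr(b, metric)
    table = np.array([[ca, a.n_total - ca], [cb, b.n_total - cb]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError(
            f"degenerate 2x2 table for metric {metric!r}: a zero row/column margin "
            "makes the chi-square statistic undefined"
        )
    res = chi2_contingency(table, correction=correction)
    return ChiSquareResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(res.dof),
        p_value=float(res.pvalue),
        table=table.astype(int),
    )
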