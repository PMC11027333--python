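"""Patient-level cohort model for PI-RADS / PSA-density biopsy triage.

A cohort is an ordered collection of :class:`PatientRecord`, one row per man
referred with suspected prostate cancer.  Each record carries the quantities
the triage rules consume — the index-lesion PI-RADS score (1–5) and the PSA
density (PSAD, serum PSA divided by prostate volume, ng/mL²) — plus the
biopsy outcome used as ground truth: ISUP grade group ≥2 is clinically
significant cancer (csPCa), grade group 1 is insignificant cancer (iPCa),
and men with a benign biopsy or no biopsy (under follow-up) count as
negative.

PSAD is stratified into four risk bands at 0.10, 0.15 and 0.20 ng/mL².
The interval convention is half-open, ``[0.10, 0.15)`` etc., so 0.20 falls
in the top band; the boundaries live in :data:`PSAD_BAND_EDGES` so the
convention is a single changeable constant.
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from datetime import date
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PSAD_BAND_EDGES",
    "PSAD_CONSISTENCY_RTOL",
    "PsadBand",
    "DiseaseStatus",
    "PatientRecord",
    "Cohort",
    "compute_psad",
    "assign_psad_band",
    "disease_status",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

#: PSAD band boundaries in ng/mL²; bands are half-open on the right:
#: [0, .10) low, [.10, .15) intermediate, [.15, .20) high, [.20, inf) very high.
PSAD_BAND_EDGES: tuple[float, float, float] = (0.10, 0.15, 0.20)

#: Relative tolerance when checking a supplied psad column against psa/volume.
PSAD_CONSISTENCY_RTOL = 1e-6


class PsadBand(IntEnum):
    """PSA-density risk band; ordering follows increasing risk."""

    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return _BAND_LABELS[self]


_BAND_LABELS = {
    PsadBand.LOW: "low",
    PsadBand.INTERMEDIATE: "intermediate",
    PsadBand.HIGH: "high",
    PsadBand.VERY_HIGH: "very_high",
}


class DiseaseStatus(Enum):
    """Ground-truth disease category of a patient."""

    CSPCA = "cspca"  # ISUP grade group >= 2
    IPCA = "ipca"  # ISUP grade group 1
    NEGATIVE = "negative"  # benign biopsy, or not biopsied (follow-up)


def compute_psad(psa: float, volume: float) -> float:
    """PSA density in ng/mL² from serum PSA (ng/mL) and gland volume (mL)."""
    if not (psa > 0):
        raise ValidationError(f"psa must be positive, got {psa!r}")
    if not (volume > 0):
        raise ValidationError(f"prostate_volume must be positive, got {volume!r}")
    return psa / volume


def assign_psad_band(psad: float) -> PsadBand:
    """Map a PSAD value to its risk band (half-open convention)."""
    if not (psad > 0):
        raise ValidationError(f"psad must be positive, got {psad!r}")
    return PsadBand(bisect_right(PSAD_BAND_EDGES, psad))


@dataclass(frozen=True)
class PatientRecord:
    """One man's clinical attributes plus ground-truth biopsy outcome.

    ``psad`` may be supplied directly or derived from ``psa`` and
    ``prostate_volume``; when both routes are available they must agree to
    :data:`PSAD_CONSISTENCY_RTOL` (relative). ``isup_grade_group`` uses 0 for
    a benign biopsy and 1–5 for ISUP groups; it must be absent when the man
    was not biopsied.
    """

    patient_id: str
    psa: float
    pirads: int
    biopsied: bool
    psad: Optional[float] = None
    prostate_volume: Optional[float] = None
    age: Optional[int] = None
    isup_grade_group: Optional[int] = None
    followup_months: Optional[float] = None
    study_date: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if self.pirads not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"patient {self.patient_id}: pirads must be in 1..5, got {self.pirads!r}"
            )
        if not (self.psa > 0):
            raise ValidationError(
                f"patient {self.patient_id}: psa must be positive, got {self.psa!r}"
            )
        if self.prostate_volume is not None and not (self.prostate_volume > 0):
            raise ValidationError(
                f"patient {self.patient_id}: prostate_volume must be positive, "
                f"got {self.prostate_volume!r}"
            )
        if self.psad is None:
            if self.prostate_volume is None:
                raise ValidationError(
                    f"patient {self.patient_id}: psad missing and cannot be derived "
                    "(no prostate_volume)"
                )
            object.__setattr__(self, "psad", self.psa / self.prostate_volume)
        else:
            if not (self.psad > 0):
                raise ValidationError(
                    f"patient {self.patient_id}: psad must be positive, got {self.psad!r}"
                )
            if self.prostate_volume is not None:
                derived = self.psa / self.prostate_volume
                if abs(self.psad - derived) > PSAD_CONSISTENCY_RTOL * self.psad:
                    raise ValidationError(
                        f"patient {self.patient_id}: psad={self.psad} inconsistent with "
                        f"psa/volume={derived:.6g}"
                    )
        if self.isup_grade_group is not None:
            if self.isup_grade_group not in range(0, 6):
                raise ValidationError(
                    f"patient {self.patient_id}: isup_grade_group must be 0..5, "
                    f"got {self.isup_grade_group!r}"
                )
            if not self.biopsied:
                raise ValidationError(
                    f"patient {self.patient_id}: isup_grade_group present but biopsied=false"
                )
        if self.followup_months is not None and self.followup_months < 0:
            raise ValidationError(
                f"patient {self.patient_id}: followup_months must be non-negative"
            )

    @property
    def psad_band(self) -> PsadBand:
        return assign_psad_band(self.psad)


def disease_status(record: PatientRecord) -> DiseaseStatus:
    """Ground-truth label: csPCa (ISUP ≥2), iPCa (ISUP 1), else negative.

    Non-biopsied men are presumed negative (they were followed without a
    positive finding); a biopsied record without an ISUP group is invalid.
    """
    if not record.biopsied:
        return DiseaseStatus.NEGATIVE
    isup = record.isup_grade_group
    if isup is None:
        raise ValidationError(
            f"patient {record.patient_id}: biopsied but isup_grade_group missing"
        )
    if isup >= 2:
        return DiseaseStatus.CSPCA
    if isup == 1:
        return DiseaseStatus.IPCA
    return DiseaseStatus.NEGATIVE


@dataclass
class Cohort:
    """Ordered, id-unique collection of patient records."""

    records: tuple[PatientRecord, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def status_counts(self) -> dict[DiseaseStatus, int]:
        out = {s: 0 for s in DiseaseStatus}
        for r in self.records:
            out[disease_status(r)] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_record_to_row(r) for r in self.records], columns=COHORT_COLUMNS)


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "psa",
    "prostate_volume",
    "psad",
    "pirads",
    "biopsied",
    "isup_grade_group",
    "followup_months",
    "study_date",
)

_MANDATORY = ("patient_id", "psa", "pirads", "biopsied")


def _record_to_row(r: PatientRecord) -> dict:
    return {
        "patient_id": r.patient_id,
        "age": "" if r.age is None else str(r.age),
        "psa": repr(float(r.psa)),
        "prostate_volume": "" if r.prostate_volume is None else repr(float(r.prostate_volume)),
        "psad": repr(float(r.psad)),
        "pirads": str(r.pirads),
        "biopsied": "true" if r.biopsied else "false",
        "isup_grade_group": "" if r.isup_grade_group is None else str(r.isup_grade_group),
        "followup_months": "" if r.followup_months is None else repr(float(r.followup_months)),
        "study_date": "" if r.study_date is None else r.study_date.isoformat(),
    }


def _parse_cell(raw: str, kind: str, row: int, col: str):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if kind == "int":
            return int(raw)
        if kind == "float":
            return float(raw)
        if kind == "bool":
            low = raw.lower()
            if low in ("true", "false"):
                return low == "true"
            raise ValueError("expected true/false")
        if kind == "date":
            return date.fromisoformat(raw)
        return raw
    except ValueError as exc:
        raise SchemaError(f"row {row}, column {col!r}: unparsable value {raw!r} ({exc})") from exc


_COLUMN_KINDS = {
    "patient_id": "str",
    "age": "int",
    "psa": "float",
    "prostate_volume": "float",
    "psad": "float",
    "pirads": "int",
    "biopsied": "bool",
    "isup_grade_group": "int",
    "followup_months": "float",
    "study_date": "date",
}


def read_cohort_csv(path: str | Path, *, metadata: Optional[Mapping] = None) -> Cohort:
    """Read a cohort from the documented CSV schema.

    Errors name the offending row (1-based, excluding the header) and column.
    Empty strings are missing values; ``psad`` is derived from psa/volume
    when absent.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        if "psad" not in reader.fieldnames and "prostate_volume" not in reader.fieldnames:
            raise SchemaError(f"{path}: need a 'psad' or 'prostate_volume' column")
        unknown = [c for c in reader.fieldnames if c not in COHORT_COLUMNS]
        if unknown:
            raise SchemaError(f"{path}: unknown column(s) {unknown}")

        records: list[PatientRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=1):
            vals = {}
            for col in reader.fieldnames:
                vals[col] = _parse_cell(row[col] or "", _COLUMN_KINDS[col], i, col)
            pid = vals.get("patient_id")
            if not pid:
                raise SchemaError(f"row {i}, column 'patient_id': missing value")
            if pid in seen:
                raise SchemaError(f"row {i}, column 'patient_id': duplicate id {pid!r}")
            seen.add(pid)
            try:
                records.append(
                    PatientRecord(
                        patient_id=pid,
                        age=vals.get("age"),
                        psa=_require(vals, "psa", i),
                        prostate_volume=vals.get("prostate_volume"),
                        psad=vals.get("psad"),
                        pirads=_require(vals, "pirads", i),
                        biopsied=_require(vals, "biopsied", i),
                        isup_grade_group=vals.get("isup_grade_group"),
                        followup_months=vals.get("followup_months"),
                        study_date=vals.get("study_date"),
                    )
                )
            except ValidationError as exc:
                raise SchemaError(f"row {i}: {exc}") from exc
    meta = dict(metadata or {})
    meta.setdefault("source", str(path))
    return Cohort(records=tuple(records), metadata=meta)


def _require(vals: dict, col: str, row: int):
    v = vals.get(col)
    if v is None:
        raise SchemaError(f"row {row}, column {col!r}: missing value")
    return v


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort; floats use full repr precision so round-trips are exact."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COHORT_COLUMNS))
        writer.writeheader()
        for r in cohort:
            writer.writerow(_record_to_row(r))
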