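"""Synthetic cohorts calibrated to a (PI-RADS group × PSAD band) cross-tab.

Real triage cohorts are usually summarized, not deposited: what a published
study leaves behind is the cross-tabulation of patient counts and csPCa
counts per (PI-RADS group, PSAD band) cell, marginal PI-RADS score counts,
ISUP grade-group totals, and median/IQR summaries of the continuous
attributes.  This module rebuilds patient-level data from exactly that
information, two ways:

* :func:`fixture_cohort` — a deterministic expansion whose cross-tab equals
  the spec cell-for-cell, whatever the seed (the seed only varies the
  continuous attributes).  Insignificant-cancer (iPCa) placement is not
  identifiable from the cross-tab alone, so it is solved from aggregate
  per-pathway iPCa detection counts via :func:`solve_ipca_allocation`.
* :func:`sample_cohort` — a seeded stochastic sampler drawing cells
  multinomially and disease status per-cell, for property tests and
  Monte-Carlo work.

Only band membership, cell counts and grade totals are calibrated exactly;
continuous PSA / volume / age values are log-normal / normal draws tuned to
the published medians and IQRs, with PSAD rejection-sampled strictly inside
its band and PSA defined as PSAD × volume so the derived quantity is
consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import Cohort, PatientRecord, PsadBand, PSAD_BAND_EDGES
from .errors import InfeasibleError, ValidationError
from .metrics import PIRADS_GROUP_LABELS, pirads_group

__all__ = [
    "CellCounts",
    "ContinuousParams",
    "CohortSpec",
    "default_cohort_spec",
    "IpcaConstraints",
    "IpcaAllocation",
    "DEFAULT_IPCA_CONSTRAINTS",
    "solve_ipca_allocation",
    "ipca_by_cell",
    "fixture_cohort",
    "sample_cohort",
]

# Canonical cell order: groups in PIRADS_GROUP_LABELS order, bands ascending.
CELL_ORDER = tuple((g, b) for g in PIRADS_GROUP_LABELS for b in PsadBand)

_GROUP_SCORES = {"1-2": (1, 2), "3": (3,), "4-5": (4, 5)}


@dataclass(frozen=True)
class CellCounts:
    n: int
    n_cspca: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_cspca <= self.n):
            raise ValidationError(f"need 0 <= n_cspca <= n, got {self.n_cspca}/{self.n}")


@dataclass(frozen=True)
class ContinuousParams:
    """Distribution parameters for the continuous patient attributes.

    ``psad_lognormal`` and ``volume_lognormal`` are (mu, sigma) of the
    underlying normal; PSA is derived as PSAD × volume.  Age is a clipped,
    rounded normal. Defaults approximate median (IQR) summaries of
    PSAD 0.11 (0.08–0.17) ng/mL², volume 54.7 (38–79) mL, age 65 (59–69) y.
    """

    psad_lognormal: tuple[float, float] = (math.log(0.11), 0.5588)
    volume_lognormal: tuple[float, float] = (math.log(54.7), 0.5425)
    age_normal: tuple[float, float] = (64.0, 7.4)
    age_range: tuple[int, int] = (40, 90)
    followup_range: tuple[float, float] = (6.0, 60.0)


@dataclass(frozen=True)
class CohortSpec:
    """Declarative recipe for a synthetic cohort.

    ``cells`` maps (group label, band) to patient/csPCa counts;
    ``pirads_counts`` splits the grouped scores into individual PI-RADS
    scores; ``cspca_isup_totals`` fixes the ISUP 2–5 grade mix among csPCa.
    """

    cells: Mapping  # (group, PsadBand) -> CellCounts
    pirads_counts: Mapping  # pirads score -> count
    ipca_total: int
    cspca_isup_totals: Mapping  # isup (2..5) -> count
    continuous: ContinuousParams = field(default_factory=ContinuousParams)

    def __post_init__(self) -> None:
        for key in CELL_ORDER:
            if key not in self.cells:
                raise ValidationError(f"spec missing cell {key}")
        for group, scores in _GROUP_SCORES.items():
            group_n = sum(self.cells[(group, b)].n for b in PsadBand)
            split_n = sum(self.pirads_counts.get(s, 0) for s in scores)
            if group_n != split_n:
                raise ValidationError(
                    f"PI-RADS split for group {group} sums to {split_n}, cells sum to {group_n}"
                )
        if sum(self.cspca_isup_totals.values()) != self.total_cspca:
            raise ValidationError(
                "csPCa ISUP grade totals must sum to the cross-tab csPCa total"
            )
        if self.ipca_total < 0 or self.ipca_total + self.total_cspca > self.total_n:
            raise ValidationError("iPCa total exceeds non-csPCa capacity")

    @property
    def total_n(self) -> int:
        return sum(c.n for c in self.cells.values())

    @property
    def total_cspca(self) -> int:
        return sum(c.n_cspca for c in self.cells.values())


def default_cohort_spec() -> CohortSpec:
    """The built-in calibration: N=2055, 623 csPCa, 196 iPCa.

    Cell counts (patients, csPCa) per PI-RADS group × PSAD band:

    ========  ========  ============  ========  =========
    group     low       intermediate  high      very high
    ========  ========  ============  ========  =========
    1-2       7/602     9/341         9/100     9/70
    3         8/76      9/63          10/40     9/27
    4-5       50/112    115/172       99/129    289/323
    ========  ========  ============  ========  =========
    """
    n = {
        "1-2": (602, 341, 100, 70),
        "3": (76, 63, 40, 27),
        "4-5": (112, 172, 129, 323),
    }
    cspca = {
        "1-2": (7, 9, 9, 9),
        "3": (8, 9, 10, 9),
        "4-5": (50, 115, 99, 289),
    }
    cells = {
        (g, b): CellCounts(n=n[g][b], n_cspca=cspca[g][b])
        for g in PIRADS_GROUP_LABELS
        for b in PsadBand
    }
    return CohortSpec(
        cells=cells,
        pirads_counts={1: 15, 2: 1098, 3: 206, 4: 238, 5: 498},
        ipca_total=196,
        cspca_isup_totals={2: 339, 3: 124, 4: 47, 5: 113},
    )


# --------------------------------------------------------------------------
# iPCa allocation
# --------------------------------------------------------------------------

# Strata over which iPCa placement is resolved; finer placement within a
# stratum is immaterial to every pathway's accounting.
_STRATA_CELLS = {
    "pr12_other": (("1-2", PsadBand.LOW), ("1-2", PsadBand.INTERMEDIATE), ("1-2", PsadBand.HIGH)),
    "pr12_very_high": (("1-2", PsadBand.VERY_HIGH),),
    "pr3_low": (("3", PsadBand.LOW),),
    "pr3_mid": (("3", PsadBand.INTERMEDIATE), ("3", PsadBand.HIGH)),
    "pr3_very_high": (("3", PsadBand.VERY_HIGH),),
    "pr45": tuple(("4-5", b) for b in PsadBand),
}


@dataclass(frozen=True)
class IpcaConstraints:
    """Aggregate iPCa detection counts the allocation must reproduce.

    ``mri_detected`` — iPCa found when biopsying all PI-RADS ≥3;
    ``risk_low_detected`` / ``risk_high_detected`` — iPCa found by the two
    risk-adapted pathways; ``total`` — iPCa in the whole cohort.
    """

    total: int
    mri_detected: int
    risk_low_detected: int
    risk_high_detected: int


DEFAULT_IPCA_CONSTRAINTS = IpcaConstraints(
    total=196, mri_detected=150, risk_low_detected=151, risk_high_detected=120
)


@dataclass(frozen=True)
class IpcaAllocation:
    """iPCa counts per stratum (see module docstring for identifiability)."""

    pr12_other: int
    pr12_very_high: int
    pr3_low: int
    pr3_mid: int
    pr3_very_high: int
    pr45: int

    def as_dict(self) -> dict:
        return {
            "pr12_other": self.pr12_other,
            "pr12_very_high": self.pr12_very_high,
            "pr3_low": self.pr3_low,
            "pr3_mid": self.pr3_mid,
            "pr3_very_high": self.pr3_very_high,
            "pr45": self.pr45,
        }

    def as_tuple(self) -> tuple:
        return (
            self.pr12_other,
            self.pr12_very_high,
            self.pr3_low,
            self.pr3_mid,
            self.pr3_very_high,
            self.pr45,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def solve_ipca_allocation(
    spec: CohortSpec,
    constraints: Optional[IpcaConstraints] = None,
    *,
    pr3_low: int = 0,
    pr3_very_high: int = 0,
) -> IpcaAllocation:
    """Solve stratum iPCa counts from aggregate pathway detection counts.

    The four linear constraints leave two degrees of freedom, fixed by the
    ``pr3_low`` and ``pr3_very_high`` keyword defaults (both 0).  Raises
    :class:`InfeasibleError` naming the violated constraint when no
    non-negative, capacity-respecting solution exists.
    """
    con = constraints or IpcaConstraints(
        total=spec.ipca_total,
        mri_detected=DEFAULT_IPCA_CONSTRAINTS.mri_detected,
        risk_low_detected=DEFAULT_IPCA_CONSTRAINTS.risk_low_detected,
        risk_high_detected=DEFAULT_IPCA_CONSTRAINTS.risk_high_detected,
    )
    if con.total != spec.ipca_total:
        raise InfeasibleError(
            f"constraint total={con.total} contradicts spec iPCa total {spec.ipca_total}"
        )
    c, e = pr3_low, pr3_very_high
    f = con.risk_high_detected - e
    d = con.mri_detected - con.risk_high_detected - c
    b = con.risk_low_detected - con.mri_detected + c
    a = con.total - con.mri_detected - b
    alloc = IpcaAllocation(
        pr12_other=a, pr12_very_high=b, pr3_low=c, pr3_mid=d, pr3_very_high=e, pr45=f
    )
    for name, value in alloc.as_dict().items():
        if value < 0:
            raise InfeasibleError(
                f"iPCa allocation infeasible: stratum {name!r} would need {value} < 0 "
                f"(constraints {con})"
            )
        cap = sum(spec.cells[key].n - spec.cells[key].n_cspca for key in _STRATA_CELLS[name])
        if value > cap:
            raise InfeasibleError(
                f"iPCa allocation infeasible: stratum {name!r} needs {value} but only "
                f"{cap} non-csPCa slots exist"
            )
    return alloc


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Deterministic integer apportionment of `total` by `weights`."""
    w = np.asarray(weights, dtype=float)
    if total == 0:
        return [0] * len(w)
    if w.sum() <= 0:
        raise ValidationError("cannot apportion over all-zero weights")
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = total - int(base.sum())
    # ties broken by position for determinism
    order = np.argsort(-(quota - base), kind="stable")
    for idx in order[:rem]:
        base[idx] += 1
    return base.tolist()


def ipca_by_cell(spec: CohortSpec, allocation: IpcaAllocation) -> dict:
    """Spread stratum iPCa counts over cells, proportional to benign capacity."""
    out = {key: 0 for key in CELL_ORDER}
    for stratum, cells in _STRATA_CELLS.items():
        count = getattr(allocation, stratum)
        caps = [spec.cells[key].n - spec.cells[key].n_cspca for key in cells]
        for key, k in zip(cells, _largest_remainder(count, caps)):
            out[key] = k
    return out


# --------------------------------------------------------------------------
# Attribute generation
# --------------------------------------------------------------------------

#: generated PSAD values stay at least this margin inside their band
_BAND_MARGIN = 1e-4
_PSAD_FLOOR = 0.01


def _band_bounds(band: PsadBand) -> tuple[float, float]:
    edges = (0.0,) + PSAD_BAND_EDGES + (float("inf"),)
    return edges[band], edges[band + 1]


def _draw_psad_in_band(rng: np.random.Generator, band: PsadBand, size: int, params: ContinuousParams) -> np.ndarray:
    """Log-normal PSAD draws rejection-sampled strictly inside the band."""
    lo, hi = _band_bounds(band)
    lo = max(lo + _BAND_MARGIN, _PSAD_FLOOR)
    hi = hi - _BAND_MARGIN if math.isfinite(hi) else hi
    mu, sigma = params.psad_lognormal
    out = np.empty(size)
    filled = 0
    for _ in range(200):
        if filled >= size:
            break
        draw = rng.lognormal(mu, sigma, size=max(4 * (size - filled), 32))
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(good.size, size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    if filled < size:  # pathological band; fall back to uniform inside it
        span_hi = hi if math.isfinite(hi) else lo * 4
        out[filled:] = rng.uniform(lo, span_hi, size=size - filled)
    return out


def _draw_common(rng: np.random.Generator, band: PsadBand, size: int, params: ContinuousParams):
    psad = _draw_psad_in_band(rng, band, size, params)
    mu_v, sg_v = params.volume_lognormal
    volume = rng.lognormal(mu_v, sg_v, size=size)
    psa = psad * volume
    a_lo, a_hi = params.age_range
    mean_a, sd_a = params.age_normal
    age = np.clip(np.rint(rng.normal(mean_a, sd_a, size=size)), a_lo, a_hi).astype(int)
    return psad, volume, psa, age


def _pirads_scores_for_cells(spec: CohortSpec, cell_n: Mapping) -> dict:
    """Per cell, how many patients carry each individual PI-RADS score.

    The minority score of a grouped pair (PI-RADS 1 within 1–2; 4 within
    4–5) is apportioned across the group's cells by cell size.
    """
    out = {}
    for group, scores in _GROUP_SCORES.items():
        cells = [key for key in CELL_ORDER if key[0] == group]
        sizes = [cell_n[key] for key in cells]
        if len(scores) == 1:
            for key in cells:
                out[key] = {scores[0]: cell_n[key]}
            continue
        lo_score, hi_score = scores
        lo_total = spec.pirads_counts.get(lo_score, 0)
        lo_per_cell = _largest_remainder(lo_total, sizes) if sum(sizes) else [0] * len(cells)
        for key, k in zip(cells, lo_per_cell):
            out[key] = {lo_score: k, hi_score: cell_n[key] - k}
    return out


def _grade_pool(spec: CohortSpec) -> list[int]:
    """csPCa ISUP grades, ascending, assigned to cells in risk order.

    Iterating cells from (PI-RADS 1-2, low) to (4-5, very high) and consuming
    this pool sequentially weights higher grades toward higher-risk cells —
    a labelled heuristic, since the grade-by-cell breakdown is not part of
    the calibration.
    """
    pool: list[int] = []
    for grade in sorted(spec.cspca_isup_totals):
        pool.extend([grade] * spec.cspca_isup_totals[grade])
    return pool


def fixture_cohort(
    spec: CohortSpec,
    seed: int = 0,
    allocation: Optional[IpcaAllocation] = None,
) -> Cohort:
    """Deterministic patient-level expansion of the spec.

    The cross-tab of the result equals the spec exactly for every seed; the
    seed only drives the continuous attributes.  Biopsy status: all
    PI-RADS 3–5 men and all cancer-bearing PI-RADS 1–2 men are biopsied;
    remaining PI-RADS 1–2 men are unbiopsied with ≥6 months follow-up
    (presumed negative).
    """
    allocation = allocation if allocation is not None else solve_ipca_allocation(spec)
    if allocation.total != spec.ipca_total:
        raise ValidationError("allocation total does not match spec iPCa total")
    ipca_cells = ipca_by_cell(spec, allocation)
    cell_n = {key: spec.cells[key].n for key in CELL_ORDER}
    pirads_split = _pirads_scores_for_cells(spec, cell_n)
    grade_pool = _grade_pool(spec)

    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    grade_idx = 0
    pid = 0
    for group, band in CELL_ORDER:
        cc = spec.cells[(group, band)]
        n_ipca = ipca_cells[(group, band)]
        n_benign = cc.n - cc.n_cspca - n_ipca
        if n_benign < 0:
            raise ValidationError(f"cell ({group}, {band.label}) over capacity")
        grades = grade_pool[grade_idx : grade_idx + cc.n_cspca]
        grade_idx += cc.n_cspca
        # higher PI-RADS score first so, within a grouped cell, the more
        # suspicious score coincides with the cancer-bearing records
        scores: list[int] = []
        for score in sorted(pirads_split[(group, band)], reverse=True):
            scores.extend([score] * pirads_split[(group, band)][score])
        psad, volume, psa, age = _draw_common(rng, band, cc.n, spec.continuous)
        isups = sorted(grades, reverse=True) + [1] * n_ipca + [None] * n_benign
        for k in range(cc.n):
            pid += 1
            isup = isups[k]
            has_cancer = isup is not None and isup >= 1
            biopsied = group != "1-2" or has_cancer
            records.append(
                PatientRecord(
                    patient_id=f"P{pid:05d}",
                    age=int(age[k]),
                    psa=float(psa[k]),
                    prostate_volume=float(volume[k]),
                    psad=float(psad[k]),
                    pirads=scores[k],
                    biopsied=biopsied,
                    isup_grade_group=(isup if biopsied else None) if isup is not None else (0 if biopsied else None),
                    followup_months=None if biopsied else float(np.round(rng.uniform(*spec.continuous.followup_range), 1)),
                )
            )
    return Cohort(
        records=tuple(records),
        metadata={"source": "fixture", "seed": int(seed), "ipca_allocation": allocation.as_dict()},
    )


def sample_cohort(spec: CohortSpec, n: int, seed: int) -> Cohort:
    """Seeded stochastic cohort: cells multinomial, disease trinomial per cell.

    Cell probabilities are proportional to the spec's patient counts; within
    each drawn cell, status (csPCa / iPCa / negative) follows the spec's cell
    prevalences, csPCa grades follow the global ISUP mix, and individual
    PI-RADS scores follow the group's score split.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    allocation = solve_ipca_allocation(spec)
    ipca_cells = ipca_by_cell(spec, allocation)
    total = spec.total_n
    probs = np.array([spec.cells[key].n / total for key in CELL_ORDER])
    counts = rng.multinomial(n, probs)

    grades = np.array(sorted(spec.cspca_isup_totals))
    grade_p = np.array([spec.cspca_isup_totals[g] for g in grades], dtype=float)
    grade_p /= grade_p.sum()

    records: list[PatientRecord] = []
    pid = 0
    for (group, band), m in zip(CELL_ORDER, counts):
        if m == 0:
            continue
        cc = spec.cells[(group, band)]
        p_cs = cc.n_cspca / cc.n if cc.n else 0.0
        p_ip = ipca_cells[(group, band)] / cc.n if cc.n else 0.0
        status = rng.multinomial(m, [p_cs, p_ip, max(1.0 - p_cs - p_ip, 0.0)])
        n_cs, n_ip, n_neg = (int(x) for x in status)
        scores_spec = _GROUP_SCORES[group]
        if len(scores_spec) == 2:
            lo_s, hi_s = scores_spec
            lo_tot = spec.pirads_counts.get(lo_s, 0)
            hi_tot = spec.pirads_counts.get(hi_s, 0)
            p_lo = lo_tot / (lo_tot + hi_tot) if lo_tot + hi_tot else 0.0
            score_draw = np.where(rng.random(m) < p_lo, lo_s, hi_s)
        else:
            score_draw = np.full(m, scores_spec[0])
        psad, volume, psa, age = _draw_common(rng, band, m, spec.continuous)
        isups = (
            list(rng.choice(grades, size=n_cs, p=grade_p))
            + [1] * n_ip
            + [None] * n_neg
        )
        for k in range(m):
            pid += 1
            isup = isups[k]
            has_cancer = isup is not None and isup >= 1
            biopsied = group != "1-2" or has_cancer
            records.append(
                PatientRecord(
                    patient_id=f"S{pid:06d}",
                    age=int(age[k]),
                    psa=float(psa[k]),
                    prostate_volume=float(volume[k]),
                    psad=float(psad[k]),
                    pirads=int(score_draw[k]),
                    biopsied=biopsied,
                    isup_grade_group=(int(isup) if isup is not None else 0) if biopsied else None,
                    followup_months=None if biopsied else float(np.round(rng.uniform(*spec.continuous.followup_range), 1)),
                )
            )
    return Cohort(
        records=tuple(records),
        metadata={"source": "sample", "seed": int(seed), "n_requested": int(n)},
    )
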