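"""Decision-curve analysis for fixed biopsy strategies.

The net benefit of a strategy at a threshold probability ``p_t`` is

    NB(p_t) = TP/N − (FP/N) · p_t / (1 − p_t)

where TP is the number of clinically significant cancers the strategy
detects, FP the number of biopsies it performs without finding significant
cancer, and N the cohort size.  ``p_t`` is the minimum cancer probability at
which a decision-maker would accept a biopsy: low thresholds are
cancer-averse, high thresholds biopsy-averse.

The strategies compared here are fixed decision sets (no per-patient risk
model), so each curve is a single hyperbola in ``p_t`` and adjacent
strategies cross at the closed-form threshold ``p* = ΔTP / (ΔTP + ΔFP)``.
Curves are evaluated on a grid (default 0–0.6, step 0.001) and summarized
into dominance intervals: maximal runs of the grid on which one strategy has
the top net benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import OutcomeSummary

__all__ = [
    "FpConvention",
    "StrategyCounts",
    "net_benefit",
    "strategy_counts_from_outcome",
    "treat_all_counts",
    "treat_none_counts",
    "default_grid",
    "NetBenefitCurve",
    "decision_curves",
    "crossover_threshold",
    "DominanceInterval",
    "DominanceReport",
    "dominance_intervals",
    "TREAT_NONE",
]

TREAT_NONE = "treat_none"


class FpConvention(Enum):
    """What counts as the harm (false positive) of a biopsy strategy.

    BIOPSIED_NON_CSPCA: any biopsy not finding significant cancer (benign or
    iPCa) is a harm — the default, since finding insignificant cancer is
    overdiagnosis.  BENIGN_ONLY: only fully negative biopsies count.
    """

    BIOPSIED_NON_CSPCA = "biopsied_non_cspca"
    BENIGN_ONLY = "benign_only"


@dataclass(frozen=True)
class StrategyCounts:
    """TP/FP accounting of one fixed strategy on a cohort of size n."""

    name: str
    n: int
    tp: int
    fp: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if self.tp < 0 or self.fp < 0 or self.tp + self.fp > self.n:
            raise ValidationError(
                f"strategy {self.name!r}: need 0 <= tp + fp <= n, got tp={self.tp}, fp={self.fp}, n={self.n}"
            )


def net_benefit(counts: StrategyCounts, p_t):
    """Evaluate NB = TP/N − (FP/N)·p_t/(1−p_t); scalar or array ``p_t`` < 1."""
    p = np.asarray(p_t, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValidationError("threshold probability must lie in [0, 1)")
    nb = counts.tp / counts.n - (counts.fp / counts.n) * p / (1.0 - p)
    return float(nb) if np.isscalar(p_t) else nb


def strategy_counts_from_outcome(
    summary: OutcomeSummary,
    fp_convention: FpConvention = FpConvention.BIOPSIED_NON_CSPCA,
) -> StrategyCounts:
    """TP = csPCa detected; FP per the chosen harm convention."""
    if fp_convention is FpConvention.BIOPSIED_NON_CSPCA:
        fp = summary.fp_non_cspca
    elif fp_convention is FpConvention.BENIGN_ONLY:
        fp = summary.negative_biopsies
    else:  # pragma: no cover - enum is closed
        raise ValidationError(f"unknown FP convention {fp_convention!r}")
    return StrategyCounts(name=summary.pathway, n=summary.n_total, tp=summary.cspca_detected, fp=fp)


def treat_all_counts(n: int, n_positive: int, name: str = "treat_all") -> StrategyCounts:
    """Reference strategy biopsying everyone: TP = all positives, FP = rest."""
    return StrategyCounts(name=name, n=n, tp=n_positive, fp=n - n_positive)


def treat_none_counts(n: int, name: str = TREAT_NONE) -> StrategyCounts:
    """Reference strategy biopsying no one: identically zero net benefit."""
    return StrategyCounts(name=name, n=n, tp=0, fp=0)


def default_grid(stop: float = 0.6, step: float = 0.001) -> np.ndarray:
    """Threshold grid [0, stop] inclusive; must stay strictly below 1."""
    if not (0 < stop < 1) or step <= 0:
        raise ValidationError("need 0 < stop < 1 and step > 0")
    return np.round(np.arange(0.0, stop + step / 2, step), 12)


@dataclass
class NetBenefitCurve:
    """Net benefit of each strategy over a shared threshold grid."""

    thresholds: np.ndarray
    values: dict  # name -> ndarray aligned with thresholds
    strategies: dict  # name -> StrategyCounts

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"threshold": self.thresholds})
        for name, vals in self.values.items():
            df[name] = vals
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def decision_curves(
    strategies: Sequence[StrategyCounts],
    grid: Optional[np.ndarray] = None,
    *,
    add_treat_none: bool = True,
) -> NetBenefitCurve:
    """Evaluate net benefit for every strategy on a common grid.

    A zero treat-none reference is appended unless already present or
    disabled; at ``p_t = 0`` every curve equals its strategy's TP/N.
    """
    if not strategies:
        raise ValidationError("need at least one strategy")
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate strategy names: {names}")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid must be non-empty")
    if np.any(grid < 0) or np.any(grid >= 1):
        raise ValidationError("threshold grid must lie strictly within [0, 1)")
    strategies = list(strategies)
    if add_treat_none and TREAT_NONE not in names:
        strategies.append(treat_none_counts(strategies[0].n))
    return NetBenefitCurve(
        thresholds=grid,
        values={s.name: net_benefit(s, grid) for s in strategies},
        strategies={s.name: s for s in strategies},
    )


def crossover_threshold(a: StrategyCounts, b: StrategyCounts) -> Optional[float]:
    """Closed-form threshold where two strategies' net benefits are equal.

    ``p* = ΔTP / (ΔTP + ΔFP)``; returns None when the curves are parallel
    (identical TP and FP deltas cancel) or the crossing falls outside [0, 1).
    """
    dtp = a.tp - b.tp
    dfp = a.fp - b.fp
    if dtp + dfp == 0:
        return None
    p = dtp / (dtp + dfp)
    return p if 0.0 <= p < 1.0 else None


@dataclass(frozen=True)
class DominanceInterval:
    """Grid sub-range [lo, hi] on which `strategies` share the top net benefit."""

    lo: float
    hi: float
    strategies: tuple  # >1 entries means a tie

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "strategies": list(self.strategies)}


@dataclass
class DominanceReport:
    intervals: list
    crossovers: dict  # (name_a, name_b) -> p*

    def to_dict(self) -> dict:
        return {
            "intervals": [iv.to_dict() for iv in self.intervals],
            "crossovers": [
                {"strategies": list(pair), "threshold": p}
                for pair, p in self.crossovers.items()
            ],
        }


_TIE_ATOL = 1e-12


def dominance_intervals(curve: NetBenefitCurve) -> DominanceReport:
    """Argmax strategy per grid point, merged into maximal intervals.

    Ties (within 1e-12) are reported explicitly as multi-strategy intervals.
    Pairwise closed-form crossovers inside the grid range are attached for
    cross-checking against the grid argmax.
    """
    if len(curve.strategies) < 2:
        raise ValidationError("dominance analysis needs at least two strategies")
    names = list(curve.values)
    matrix = np.vstack([curve.values[name] for name in names])
    best = matrix.max(axis=0)
    winners = [
        tuple(names[i] for i in range(len(names)) if matrix[i, j] >= best[j] - _TIE_ATOL)
        for j in range(matrix.shape[1])
    ]
    intervals: list[DominanceInterval] = []
    start = 0
    for j in range(1, len(winners) + 1):
        if j == len(winners) or winners[j] != winners[start]:
            intervals.append(
                DominanceInterval(
                    lo=float(curve.thresholds[start]),
                    hi=float(curve.thresholds[j - 1]),
                    strategies=winners[start],
                )
            )
            start = j
    lo, hi = float(curve.thresholds[0]), float(curve.thresholds[-1])
    crossovers = {}
    for a, b in combinations(curve.strategies.values(), 2):
        p = crossover_threshold(a, b)
        if p is not None and lo <= p <= hi:
            crossovers[(a.name, b.name)] = p
    return DominanceReport(intervals=intervals, crossovers=crossovers)
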