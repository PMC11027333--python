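import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psadpath import (
    FpConvention,
    StrategyCounts,
    ValidationError,
    crossover_threshold,
    decision_curves,
    default_grid,
    dominance_intervals,
    net_benefit,
    strategy_counts_from_outcome,
    treat_all_counts,
    treat_none_counts,
)

BIOPSY_ALL = StrategyCounts(name="biopsy_all", n=2055, tp=623, fp=1432)
MRI = StrategyCounts(name="mri_focused", n=2055, tp=589, fp=353)
RISK_LOW = StrategyCounts(name="risk_low", n=2055, tp=590, fp=346)
RISK_HIGH = StrategyCounts(name="risk_high", n=2055, tp=562, fp=201)
FOUR = (BIOPSY_ALL, MRI, RISK_LOW, RISK_HIGH)


class TestNetBenefit:
    def test_at_zero_threshold_equals_tp_over_n(self):
        assert net_benefit(BIOPSY_ALL, 0.0) == pytest.approx(623 / 2055)

    def test_direct_arithmetic(self):
        # TP/N - (FP/N) * p/(1-p) with the MRI-pathway counts at p=0.10
        expected = 589 / 2055 - (353 / 2055) * (0.10 / 0.90)
        assert net_benefit(MRI, 0.10) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.26753, abs=5e-5)

    def test_treat_none_is_identically_zero(self):
        zero = treat_none_counts(2055)
        assert np.all(net_benefit(zero, default_grid()) == 0.0)

    def test_threshold_of_one_rejected(self):
        with pytest.raises(ValidationError):
            net_benefit(BIOPSY_ALL, 1.0)

    def test_may_be_negative(self):
        assert net_benefit(BIOPSY_ALL, 0.5) < 0

    @settings(max_examples=100, derandomize=True)
    @given(
        p1=st.floats(min_value=0.0, max_value=0.98),
        p2=st.floats(min_value=0.0, max_value=0.98),
    )
    def test_strictly_decreasing_in_threshold_when_fp_positive(self, p1, p2):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-9:  # below this the FP term underflows float64
            assert net_benefit(MRI, hi) < net_benefit(MRI, lo)
        else:
            assert net_benefit(MRI, hi) <= net_benefit(MRI, lo)

    @settings(max_examples=100, derandomize=True)
    @given(
        prev=st.floats(min_value=0.01, max_value=0.99),
        p_t=st.floats(min_value=0.0, max_value=0.95),
    )
    def test_treat_all_matches_closed_form(self, prev, p_t):
        """Treat-all NB = prevalence - (1-prevalence) * p/(1-p)."""
        n = 10000
        pos = int(round(prev * n))
        strat = treat_all_counts(n, pos)
        closed = pos / n - (1 - pos / n) * p_t / (1 - p_t)
        assert net_benefit(strat, p_t) == pytest.approx(closed, abs=1e-12)


class TestStrategyCounts:
    def test_from_outcome_default_convention(self, outcomes):
        s = strategy_counts_from_outcome(outcomes["risk_low"])
        assert (s.tp, s.fp) == (590, 346)
        s = strategy_counts_from_outcome(outcomes["biopsy_all"])
        assert (s.tp, s.fp) == (623, 1432)

    def test_benign_only_convention(self, outcomes):
        s = strategy_counts_from_outcome(outcomes["risk_low"], FpConvention.BENIGN_ONLY)
        assert (s.tp, s.fp) == (590, 195)  # 936 biopsied - 590 csPCa - 151 iPCa

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            StrategyCounts(name="bad", n=10, tp=8, fp=5)


class TestDecisionCurves:
    def test_curve_equals_pointwise_net_benefit(self):
        grid = default_grid()
        curve = decision_curves([RISK_LOW], grid, add_treat_none=False)
        np.testing.assert_allclose(curve.values["risk_low"], net_benefit(RISK_LOW, grid))

    def test_treat_none_reference_appended(self):
        curve = decision_curves(FOUR)
        assert np.all(curve.values["treat_none"] == 0.0)

    def test_biopsy_all_maximal_at_small_threshold(self):
        curve = decision_curves(FOUR)
        j = int(np.argmin(np.abs(curve.thresholds - 0.01)))
        col = {name: vals[j] for name, vals in curve.values.items()}
        assert max(col, key=col.get) == "biopsy_all"

    @pytest.mark.parametrize("bad_grid", [np.array([]), np.array([0.5, 1.0]), np.array([-0.1])])
    def test_bad_grids_rejected(self, bad_grid):
        with pytest.raises(ValidationError):
            decision_curves(FOUR, bad_grid)

    def test_empty_strategy_list_rejected(self):
        with pytest.raises(ValidationError):
            decision_curves([])


class TestDominance:
    def test_crossover_biopsy_all_vs_risk_low(self):
        # delta TP / (delta TP + delta FP) = 33 / (33 + 1086)
        assert crossover_threshold(BIOPSY_ALL, RISK_LOW) == pytest.approx(33 / 1119)

    def test_crossover_risk_low_vs_risk_high(self):
        assert crossover_threshold(RISK_LOW, RISK_HIGH) == pytest.approx(28 / 173)

    def test_parallel_strategies_have_no_crossover(self):
        assert crossover_threshold(RISK_LOW, RISK_LOW) is None

    def test_intervals_partition_grid_and_order(self):
        report = dominance_intervals(decision_curves(FOUR))
        solo = [iv for iv in report.intervals if len(iv.strategies) == 1]
        winners = [iv.strategies[0] for iv in solo]
        # comparator dominates at cancer-averse thresholds, then the low- and
        # high-threshold risk pathways take over in sequence
        assert winners[:1] == ["biopsy_all"]
        assert "risk_low" in winners and "risk_high" in winners
        assert winners.index("risk_low") < winners.index("risk_high")
        assert report.intervals[0].lo == 0.0
        assert report.intervals[-1].hi == pytest.approx(0.6)

    def test_grid_argmax_agrees_with_closed_form_crossovers(self):
        """Interval edges sit within one grid step of the analytic crossing."""
        grid = default_grid()
        step = float(grid[1] - grid[0])
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 3000
            strats = [
                StrategyCounts(name=f"s{i}", n=n, tp=int(tp), fp=int(fp))
                for i, (tp, fp) in enumerate(
                    zip(rng.integers(100, 900, 3), rng.integers(100, 2000, 3))
                )
            ]
            if len({(s.tp, s.fp) for s in strats}) < 3:
                continue
            report = dominance_intervals(decision_curves(strats, grid, add_treat_none=False))
            for prev, nxt in zip(report.intervals, report.intervals[1:]):
                a = prev.strategies[-1]
                b = nxt.strategies[0]
                if a == b or len(prev.strategies) > 1 or len(nxt.strategies) > 1:
                    continue
                p = crossover_threshold(
                    *(s for s in strats if s.name in (a, b))
                )
                if p is not None:
                    boundary = (prev.hi + nxt.lo) / 2
                    assert abs(p - boundary) <= step

    def test_identical_strategies_tie_over_whole_grid(self):
        twin = StrategyCounts(name="twin", n=2055, tp=590, fp=346)
        report = dominance_intervals(decision_curves([RISK_LOW, twin], add_treat_none=False))
        assert len(report.intervals) == 1
        assert set(report.intervals[0].strategies) == {"risk_low", "twin"}

    def test_needs_two_strategies(self):
        with pytest.raises(ValidationError):
            dominance_intervals(decision_curves([RISK_LOW], add_treat_none=False))
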