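import numpy as np
import pytest

from psadpath import (
    Cohort,
    PsadBand,
    ValidationError,
    apply_pathway,
    builtin_pathways,
    compare_chi_square,
    cross_tabulate,
    default_cohort_spec,
    get_builtin_pathway,
    outcome_table,
    pathway_outcomes,
    sample_cohort,
)
from psadpath.metrics import OutcomeSummary

# Calibrated cross-tab: (patients, csPCa) per (PI-RADS group, PSAD band)
EXPECTED_CELLS = {
    ("1-2", PsadBand.LOW): (602, 7),
    ("1-2", PsadBand.INTERMEDIATE): (341, 9),
    ("1-2", PsadBand.HIGH): (100, 9),
    ("1-2", PsadBand.VERY_HIGH): (70, 9),
    ("3", PsadBand.LOW): (76, 8),
    ("3", PsadBand.INTERMEDIATE): (63, 9),
    ("3", PsadBand.HIGH): (40, 10),
    ("3", PsadBand.VERY_HIGH): (27, 9),
    ("4-5", PsadBand.LOW): (112, 50),
    ("4-5", PsadBand.INTERMEDIATE): (172, 115),
    ("4-5", PsadBand.HIGH): (129, 99),
    ("4-5", PsadBand.VERY_HIGH): (323, 289),
}


class TestCrossTab:
    def test_fixture_reproduces_every_cell(self, fixture):
        ct = cross_tabulate(fixture)
        for (group, band), (n, c) in EXPECTED_CELLS.items():
            assert ct.cell(group, band) == (n, c), (group, band)
        assert ct.grand_total == 2055
        assert ct.total_cspca == 623

    def test_margins_equal_cell_sums(self, fixture):
        ct = cross_tabulate(fixture)
        assert ct.row_totals.tolist() == [1113, 206, 736]
        assert ct.col_totals.tolist() == [790, 576, 269, 420]
        assert ct.row_totals.sum() == ct.grand_total

    def test_single_patient_cohort(self):
        cohort = sample_cohort(default_cohort_spec(), n=1, seed=0)
        ct = cross_tabulate(cohort)
        assert ct.grand_total == 1
        assert ct.n.sum() == 1

    def test_partition_additivity(self):
        """Cross-tabs of a cohort partition sum cell-wise to the whole."""
        cohort = sample_cohort(default_cohort_spec(), n=300, seed=5)
        half = len(cohort) // 2
        a = Cohort(records=cohort.records[:half])
        b = Cohort(records=cohort.records[half:])
        whole, ca, cb = (cross_tabulate(x) for x in (cohort, a, b))
        np.testing.assert_array_equal(whole.n, ca.n + cb.n)
        np.testing.assert_array_equal(whole.n_cspca, ca.n_cspca + cb.n_cspca)


class TestPathwayOutcomes:
    @pytest.mark.parametrize(
        "name,avoided,detected,missed,ipca_det",
        [
            ("biopsy_all", 0, 623, 0, 196),
            ("mri_focused", 1113, 589, 34, 150),
            ("risk_low", 1119, 590, 33, 151),
            ("risk_high", 1292, 562, 61, 120),
        ],
    )
    def test_fixture_outcome_counts(self, outcomes, name, avoided, detected, missed, ipca_det):
        r = outcomes[name]
        assert (r.n_avoided, r.cspca_detected, r.cspca_missed, r.ipca_detected) == (
            avoided,
            detected,
            missed,
            ipca_det,
        )

    def test_negative_biopsy_accounting(self, outcomes):
        # fp_non_cspca matches biopsied-minus-csPCa; benign-only is stricter
        assert outcomes["biopsy_all"].negative_biopsies == 1236
        assert outcomes["mri_focused"].fp_non_cspca == 353
        assert outcomes["risk_low"].fp_non_cspca == 346
        assert outcomes["risk_high"].fp_non_cspca == 201

    def test_mismatched_ids_rejected(self, fixture):
        decisions = apply_pathway(get_builtin_pathway("risk_low"), fixture)
        short = Cohort(records=fixture.records[:10])
        with pytest.raises(ValidationError, match="cover"):
            pathway_outcomes(short, decisions)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_identities(self, seed):
        """Counts partition the cohort for every pathway on random cohorts."""
        cohort = sample_cohort(default_cohort_spec(), n=250, seed=seed)
        total_cs = sum(1 for _ in cohort if _.biopsied and _.isup_grade_group >= 2)
        for r in outcome_table(cohort, builtin_pathways()):
            assert r.n_biopsied + r.n_avoided == r.n_total == len(cohort)
            assert r.cspca_detected + r.cspca_missed == total_cs
            assert r.fp_non_cspca == r.negative_biopsies + r.ipca_detected
            assert r.n_biopsied == r.cspca_detected + r.fp_non_cspca

    def test_monotonicity_under_nested_decisions(self):
        """A strictly more selective pathway detects less and avoids more."""
        cohort = sample_cohort(default_cohort_spec(), n=500, seed=9)
        rows = {r.pathway: r for r in outcome_table(cohort, builtin_pathways())}
        for narrow, wide in [("risk_high", "risk_low"), ("risk_low", "biopsy_all"), ("mri_focused", "biopsy_all")]:
            assert rows[narrow].cspca_detected <= rows[wide].cspca_detected
            assert rows[narrow].n_avoided >= rows[wide].n_avoided


class TestOutcomeTable:
    def test_order_preserved_and_duplicates_identical(self, fixture):
        defs = [get_builtin_pathway("risk_low"), get_builtin_pathway("risk_low")]
        rows = outcome_table(fixture, defs)
        assert len(rows) == 2 and rows[0] == rows[1]

    def test_empty_definition_list_rejected(self, fixture):
        with pytest.raises(ValidationError):
            outcome_table(fixture, [])


def _pearson_chi2(table):
    """Independent closed-form oracle for the 2x2 Pearson statistic."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def _summary(name, n, count):
    return OutcomeSummary(
        pathway=name,
        n_total=n,
        n_biopsied=count,
        n_avoided=n - count,
        cspca_detected=count,
        cspca_missed=0,
        ipca_detected=0,
        ipca_avoided=0,
        negative_biopsies=0,
        fp_non_cspca=0,
    )


class TestChiSquare:
    def test_against_closed_form_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(50, 5000))
            ca, cb = (int(rng.integers(1, n)) for _ in range(2))
            res = compare_chi_square(_summary("a", n, ca), _summary("b", n, cb), "cspca_detected")
            assert res.statistic == pytest.approx(
                _pearson_chi2([[ca, n - ca], [cb, n - cb]]), abs=1e-8
            )
            assert res.degrees_of_freedom == 1

    def test_fixture_detection_comparison(self, outcomes):
        """csPCa detection, biopsy-all vs risk-low: chi2=1.2737, p=.259."""
        res = compare_chi_square(outcomes["biopsy_all"], outcomes["risk_low"], "cspca_detected")
        assert res.statistic == pytest.approx(1.273686, abs=1e-4)
        assert res.p_value == pytest.approx(0.259077, abs=1e-4)

    def test_identical_rows_give_zero_statistic(self, outcomes):
        res = compare_chi_square(outcomes["risk_low"], outcomes["risk_low"], "cspca_detected")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        a = _summary("a", 10, 0)
        b = _summary("b", 10, 0)
        with pytest.raises(ValidationError, match="margin"):
            compare_chi_square(a, b, "cspca_detected")

    def test_unknown_metric_and_size_mismatch(self, outcomes):
        with pytest.raises(ValidationError):
            compare_chi_square(outcomes["risk_low"], outcomes["risk_high"], "nonsense")
        with pytest.raises(ValidationError):
            compare_chi_square(outcomes["risk_low"], _summary("b", 99, 5), "cspca_detected")

    def test_p_decreases_as_counts_diverge(self):
        n = 2000
        base = _summary("a", n, 500)
        p_prev = 1.0
        for cb in (500, 530, 580, 700):
            p = compare_chi_square(base, _summary("b", n, cb), "cspca_detected").p_value
            assert p <= p_prev + 1e-12
            p_prev = p
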