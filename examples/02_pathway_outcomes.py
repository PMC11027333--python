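"""Score the four built-in biopsy pathways on the calibrated cohort.

Rates use the whole cohort (N) as denominator: 'avoid' is the share of men
spared a biopsy, 'missed' the share of the cohort whose significant cancer
the pathway fails to biopsy, 'iPCa' the overdiagnosis burden.
"""

import psadpath as pp

cohort = pp.fixture_cohort(pp.default_cohort_spec(), seed=1)
rows = pp.outcome_table(cohort, pp.builtin_pathways())

for r in rows:
    print(f"{r.pathway:12s} avoid={r.n_avoided:4d} ({100*r.avoidance_rate:4.1f}%)  "
          f"csPCa={r.cspca_detected} ({100*r.cspca_detection_rate:.1f}%)  "
          f"missed={r.cspca_missed} ({100*r.cspca_missed_rate:.1f}%)  "
          f"iPCa={r.ipca_detected}")

# Are detection rates of biopsy-all and the low-threshold pathway
# statistically distinguishable? (Pearson chi-square, df=1)
by_name = {r.pathway: r for r in rows}
res = pp.compare_chi_square(by_name["biopsy_all"], by_name["risk_low"], "cspca_detected")
print(f"\nbiopsy_all vs risk_low csPCa detection: chi2={res.statistic:.3f}, "
      f"p={res.p_value:.3f} -> no significant loss of detection")
res = pp.compare_chi_square(by_name["biopsy_all"], by_name["risk_high"], "cspca_missed")
print(f"biopsy_all vs risk_high missed csPCa:   chi2={res.statistic:.3f}, "
      f"p={res.p_value:.2g} -> the high threshold does miss cancers")
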