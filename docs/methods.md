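# Methods

## Problem and model

Men referred with suspected prostate cancer receive a multiparametric MRI
scored on the PI-RADS 1–5 scale, and most also have a serum PSA and a
gland-volume estimate from which PSA density (PSAD = PSA / volume, ng/mL²)
is derived. The clinical question is *who to biopsy*: biopsying everyone
finds every clinically significant cancer (csPCa, ISUP grade group ≥2) but
subjects many men to an invasive procedure that finds either nothing or an
insignificant cancer (iPCa, ISUP group 1) whose detection is itself a harm
(overdiagnosis).

The package compares *fixed* biopsy-selection pathways defined on the
(PI-RADS, PSAD band) grid. PSAD is banded at 0.10, 0.15 and 0.20 ng/mL²
into low / intermediate / high / very-high risk. Four pathways are built
in: biopsy-all; MRI-focused (biopsy iff PI-RADS ≥3); a risk-adapted
low-threshold rule (PI-RADS 1–2 biopsied only at PSAD ≥0.20, PI-RADS 3 at
PSAD ≥0.10, PI-RADS 4–5 always); and a risk-adapted high-threshold rule
(PI-RADS 3 only at PSAD ≥0.20, PI-RADS 4–5 always). Arbitrary pathways of
the same form can be supplied as YAML/JSON documents; rules are evaluated
first-match-wins with a mandatory default so every pathway is total.

Ground truth per patient is the biopsy ISUP grade group (0 = benign), with
non-biopsied men presumed negative under follow-up — the standard working
assumption for triage cohorts of this kind, and an optimistic one: a
pathway's "missed csPCa" is bounded below by cancers the original cohort
itself never detected.

## Band-boundary convention

The band intervals are half-open on the right: [0.10, 0.15), [0.15, 0.20),
[0.20, ∞). The alternative closed/open reading changes only patients
sitting exactly on an edge; the synthetic generator keeps every PSAD value
a strict margin (10⁻⁴) away from the edges so no fixture result depends on
the convention. The edges live in a single constant
(`psadpath.cohort.PSAD_BAND_EDGES`).

## Outcome accounting

For a pathway applied to a cohort of size N, the package reports biopsies
performed and avoided, csPCa detected and missed, iPCa detected and
avoided, and two "false positive" style columns:

* `negative_biopsies` — biopsies finding no cancer of any grade;
* `fp_non_cspca` — biopsies not finding csPCa (benign **plus** iPCa).

Both are kept because published outcome tables are ambiguous between the
two: for selective pathways "negative biopsy" typically means
biopsied-minus-csPCa (our `fp_non_cspca`), while for the biopsy-all
comparator it means cancer-free (our `negative_biopsies`). All headline
rates use N as denominator; per-biopsy yields are available as secondary
properties.

Pairs of pathways on the same cohort are compared with the Pearson
chi-square test on the 2×2 table `[[count, N−count], …]`, no Yates
correction by default (N is large; a `correction` flag exists). P-values
are reported at full precision and not adjusted for multiplicity.

## Decision-curve analysis

Net benefit at threshold probability `p_t` is

```
NB(p_t) = TP/N − (FP/N) · p_t / (1 − p_t)
```

with TP = csPCa detected and FP set by a convention: the default
`BIOPSIED_NON_CSPCA` counts any biopsy without csPCa as harm (iPCa
detection is overdiagnosis); `BENIGN_ONLY` is available. Because the
strategies are fixed decision sets rather than per-patient risk models,
each curve is a single hyperbola and two strategies cross at the exact
threshold `p* = ΔTP / (ΔTP + ΔFP)`. Curves are evaluated on a grid
(default 0–0.6 in steps of 0.001, the conventional plotting range) plus
treat-all / treat-none references; dominance intervals come from the grid
argmax, ties (within 10⁻¹²) reported explicitly, and the closed-form
crossovers are attached for cross-checking — grid switches and analytic
crossings agree to within one grid step by construction.

On the built-in calibration the computed dominance structure is: biopsy-all
best below p_t ≈ 33/1119 ≈ 2.9%, the low-threshold risk pathway best up to
≈ 28/173 ≈ 16.2%, the high-threshold pathway beyond. Published analyses of
the same counts using patient-level data and external DCA software quote
slightly different switch points (≈3.6% and ≈13.9%); the closed form above
is exact for the count data the package is given, so we report our computed
crossovers and do not force agreement.

## Synthetic cohort generator

No patient-level data are available for the cohort the calibration
describes; the generator rebuilds one from its published summaries. The
defaults encode a cohort of N = 2055 with 623 csPCa and 196 iPCa, the full
3×4 (PI-RADS group × PSAD band) patient/csPCa cross-tabulation, the
PI-RADS score split (15/1098/206/238/498 for scores 1–5), and the ISUP
grade mix among csPCa (339/124/47/113 for groups 2–5).

Two generation modes:

* `fixture_cohort` — deterministic expansion whose cross-tab equals the
  spec **exactly for every seed**; the seed drives only the continuous
  attributes. This is the object of all exact calibration checks.
* `sample_cohort` — multinomial cells and per-cell trinomial disease
  status at the spec's prevalences, for property tests and Monte-Carlo.

**iPCa placement.** The per-cell location of the 196 iPCa cases is not
identifiable from the cross-tab (which counts only csPCa). It is solved as
a small linear system from four aggregate constraints: total iPCa (196) and
the iPCa detected by the MRI-focused (150), low-threshold (151) and
high-threshold (120) pathways. Two degrees of freedom remain (iPCa in the
PI-RADS 3 low band and very-high band); both default to 0, giving the
stratum allocation (45, 1, 0, 30, 0, 120) across (PI-RADS 1–2 below
very-high, PI-RADS 1–2 very-high, PI-RADS 3 low, PI-RADS 3
intermediate+high, PI-RADS 3 very-high, PI-RADS 4–5). This makes the iPCa
outcome columns *calibrated reproductions, not independent checks* — the
tests label them accordingly. Within a stratum, iPCa spreads over cells
proportionally to benign capacity (largest-remainder apportionment).

**Continuous attributes.** Volume is log-normal with median 54.7 mL and
IQR-matched sigma 0.5425; PSAD is log-normal (median 0.11, sigma 0.5588)
rejection-sampled strictly inside the patient's band; PSA is defined as
PSAD × volume, so the derived-quantity invariant holds to machine
precision and the implied PSA median (~6) approximates the published 6.31
ng/mL. Age is a clipped rounded normal (64, 7.4) on [40, 90]. Only band
membership is exact; the continuous marginals are approximations and no
test asserts them beyond loose sanity bands.

**Grade placement heuristic.** The ISUP 2–5 grades among csPCa are handed
out in ascending order to cells sorted by increasing risk, so higher grades
concentrate in higher PI-RADS/PSAD cells. This is a labelled heuristic —
the grade-by-cell breakdown is not part of the calibration and nothing
downstream depends on it (pathway outcomes only distinguish ISUP ≥2 vs 1
vs benign).

**Biopsy status.** All PI-RADS 3–5 men and all cancer-bearing PI-RADS 1–2
men are biopsied; the remaining PI-RADS 1–2 men are unbiopsied with 6–60
months of follow-up. This makes ground truth observable everywhere while
mirroring the presumed-negative convention; it does not reproduce the real
mixture of clinician-driven biopsies of benign PI-RADS 1–2 men, so the
fixture's biopsied subset (1022) is smaller than a real cohort's would be.
Pathway outcome columns are unaffected (they depend on disease status and
decisions, not on who was historically biopsied).

**What passing tests show.** Exact cross-tab and outcome-column equalities
demonstrate that the rule engine and accounting are correct for the
encoded population structure; they say nothing about how the pathways
would perform on a cohort with different prevalences, PI-RADS call rates
or MRI quality. The stochastic sampler's recovery tests (cell fractions
within 3 binomial standard errors over 200 seeds of n = 2055) check the
sampler's calibration, not clinical generalizability.

## Numerical choices

* PSAD supplied and derivable from PSA/volume must agree to a relative
  1e-6; CSV floats are written with full `repr` precision so round-trips
  are bit-identical.
* Integer apportionment (PI-RADS score splits, iPCa spreading) uses
  largest-remainder with index-order tie-breaks, so all expansions are
  deterministic.
* Chi-square on a table with a zero margin raises instead of returning 0/1.
* Degenerate DCA inputs (empty grid, thresholds ≥1, fewer than two
  strategies for dominance) raise validation errors.

## Known limitations

* Strategies are binary decision sets; per-patient probability models and
  bootstrap confidence bands for net benefit are out of scope.
* Only patient-level index PI-RADS is modelled (no per-lesion structure),
  and no survival/follow-up modelling beyond the presumed-negative rule.
* The generator emulates one published cohort's structure; era sub-cohorts
  (e.g. scoring-guideline revisions) are supported only generically via
  the optional `study_date` column and external filtering.
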