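# Methods

## Scores

**Ultrasound score (X_US).** The five ATA sonographic patterns are mapped to
the upper bound of their guideline malignancy-risk band: benign and very-low
suspicion → 0, low → 0.1, intermediate → 0.2, high → 0.9. The mapping is
total and deterministic with image exactly {0, 0.1, 0.2, 0.9}; no
"unclassifiable" category is modelled. Cohort files may encode the pattern
by name or by numeric score; a numeric 0 is ambiguous between the two
zero-scoring patterns and parses as very-low.

**Genomic classifier score (X_GC).** An additive evidence model: each
detected somatic alteration is annotated with a weight in [0, 1]
(0 = no association with thyroid cancer, 1 = pathognomonic) and the score is
the sum of weights, grouped into three components (SNV/INDEL terms — one per
variant — fusion terms, CNV terms). The sum is deliberately uncapped: a
nodule with several drivers accumulates evidence, and the cutoff analysis
operates on the raw sum. Alterations missing from the weight table fall back
to a configurable `fallback_weight` (default 0) with a logged warning,
because pan-cancer panels report many variants with no thyroid-specific
annotation; treating them as errors would make real panel output unusable.

The bundled default weight table encodes the standard qualitative ordering
(BRAF V600E and RET hotspots ≥ 0.9; RAS hotspots ~0.5–0.65, with
benign-lesion-shared hotspots like HRAS Q61R below the 0.6 cutoff;
passenger-like variants ≤ 0.25). No per-alteration weight values have been
published for this scoring system — only the 0–1 scale, the source databases
and the malignant/benign prevalence-ratio rule — so these defaults are
explicitly illustrative stand-ins, and every reproduction analysis in this
package operates on reconstructed integer tables, never on the default
weights.

**Total risk score.** TRS = X_US + X_GC, with cutoffs X_US ≥ 0.9,
X_GC ≥ 0.6, TRS ≥ 0.7 (all inclusive) for dichotomization. Score
comparisons carry a 1e-9 absolute tolerance: the score lattice is decimal
and binary rounding must not flip a boundary case like 0.2 + 0.5 vs 0.7.

**Management algorithm.** Sequential: X_US = 0.9 → surgical referral,
ignoring the molecular result (molecular testing adds no specificity in the
high-suspicion stratum); otherwise surgery iff TRS ≥ 0.7. The rule is
monotone in X_GC, and on the low-to-intermediate stratum it coincides with
the plain TRS dichotomization.

## Diagnostic statistics

Metrics with empty denominators are reported as an explicit undefined marker
(`None`), never silently 0 — small-strata subgroup analyses hit empty
margins routinely.

* **Wilson score intervals** (via statsmodels, endpoints clamped to [0, 1])
  for all proportion CIs, at confidence level 0.95 by default.
* **Balanced accuracy** (sens+spec)/2 is used as "diagnostic accuracy" of a
  dichotomized score. For a single-threshold test this equals the
  trapezoidal ROC AUC (verified against an independent AUC computation in
  the tests); raw accuracy would not reproduce the reference accuracies from
  the corresponding tables.
* **Odds ratio** (tp·tn)/(fp·fn) with the log-normal (Woolf) interval,
  z = 1.96 at 95%; zero cells trigger the Haldane–Anscombe 0.5 correction on
  all four cells (statsmodels `Table2x2(shift_zeros=True)`).
* **Cutoff selection** maximizes balanced accuracy over a candidate list;
  candidates within a configurable tolerance of the maximum are tie-broken
  toward higher specificity (deterministically first-listed on exact ties),
  mirroring the practice of preferring the more specific of two
  near-equivalent cutoffs.
* **Proportion comparisons** default to the unpaired pooled two-proportion
  z-test; Fisher's exact test and a paired McNemar variant are provided.
  The package never grades conclusions on p-values.

## Reconstruction of 2×2 tables from printed percentages

Published reports print rounded percentages, not integer tables.
`reconstruct_matrix` enumerates every integer table (bounded by a known
total and/or margin bounds) whose exact metric fractions *print as* the
given values. Matching is exact rational arithmetic (`fractions.Fraction`),
with three printing conventions: `half_up` (round half away from zero at the
stated decimals — the default, which published tables usually follow),
`floor` (truncation — some published sensitivities are truncations, e.g. a
printed 80.7 for 21/26 = 80.769…), and `any` (either; for sources that mix
conventions). All solutions are returned; callers assert uniqueness when
claiming "the" table, and an **empty solution set is a meaningful result**:
it proves the printed values are jointly inconsistent, which does occur (the
pilot study's genomic-score PPV/NPV are inconsistent with its
sensitivity/specificity for every integer table; that table is therefore
recovered from sensitivity/specificity alone, with margins bounded by the
histology table, yielding a unique solution).

The bundled pilot-study reproduction (`thyrisk.study`) retains both cohort
composition views found in the source report — the histology table's 28/19
malignant/benign split and the 26/21 margins implied by every printed metric
quadruple — rather than silently resolving the discrepancy.

## Bayes prevalence projection

PPV(p) = sens·p / (sens·p + (1−spec)(1−p)) and
NPV(p) = spec·(1−p) / (spec·(1−p) + (1−sens)·p), strictly monotone in p for
non-degenerate tests, undefined markers when a test never calls
positive/negative. Projections use exact fractional sens/spec from an
integer table when one is available, falling back to user-supplied rounded
values; evaluated at a cohort's own prevalence the projection returns the
cohort-observed predictive values, a consistency identity covered by tests.
The default grid is 0.01–0.99 in steps of 0.01 with the 6–59% band (thyroid
screening to surgical referral settings) highlighted in plots. Published
range *endpoints* for such projections sometimes anchor at cohort-observed
values rather than the formula at the band edge; this package always reports
the formula value.

## Synthetic cohort generator

The generator emulates a 47-patient surgical cohort of indeterminate
nodules. Per nodule it draws, in a fixed documented order consuming exactly
four uniforms from one seeded stream (malignancy flag, histology, ultrasound
pattern, alteration event), so extending the config can never silently
reorder existing draws and identical seeds give identical cohorts.

Design choices:

* **Categorical alteration spectra.** Each histology has a distribution over
  alteration *sets* (events); one event is drawn per nodule, and remaining
  mass means panel-negative. Multi-hit profiles (NRAS+SLX4+ATM Hürthle
  tumors, BRAF+TERT papillary carcinoma) are events with several
  alterations. This was chosen over independent per-variant Bernoullis
  because it calibrates published marginal frequencies exactly in
  expectation — panel positivity 22/28 malignant and 7/19 benign, 12/28
  BRAF V600E and 4/28 RAS carriers among carcinomas — without
  double-mutation artifacts.
* **Histology mix** follows the pilot cohort's table: 28/47 carcinoma
  (11 classic PTC, 4 micro-PTC, 6 follicular-variant PTC, 1 NIFTP, 2
  Hürthle, 1 poorly differentiated, 3 medullary) and 19/47 benign (6
  follicular adenomas, 13 adenomatoid nodules). Truth is a deterministic
  function of histology, with NIFTP counted as malignant.
* **Ultrasound patterns** are drawn conditionally on malignancy with
  HIGH 9/26 | malignant vs 2/21 | benign (the conditionals implied by the
  study's reconstructed 2×2 tables; the high-suspicion pattern carries
  five-fold cancer odds).

What the generator does **not** emulate: per-nodule genotype truth (only
printed marginals are calibrated — the full genotype matrix of the source
cohort is not recoverable from text), allele fractions, nodule size or
growth, correlated ultrasound features within histologies, and the exact
published operating characteristics of X_GC/TRS (those depend on the
unpublished study weights; with the illustrative default weights the
config-implied genomic-score sensitivity is ~68%, not the published 80.7%).
Passing parameter-recovery tests therefore demonstrates internal consistency
of the simulator and scoring stack, not field performance on real nodules.
All reproduction of published statistics goes through reconstructed integer
tables instead.

## Numerical and testing choices

* Exact rational arithmetic wherever printed-value matching matters;
  float tolerances only at documented boundaries (score lattice 1e-9,
  CI endpoint clamping).
* Parameter recovery is checked at n = 20,000 nodules against the exact
  config-implied operating characteristics (enumerating the finite event
  space, no simulation on the reference side), with a ±1.5-point band.
* The Wilson interval's *pointwise exact* coverage dips to 91.4% at extreme
  small-n cells (n = 10, p = 0.05) — intrinsic to the interval — so the
  coverage guarantee is stated and tested as pooled empirical coverage
  (≥ 93%, pooled exact value 95.1%) over a seeded grid of binomial draws.
* Property-based tests (hypothesis, derandomized) cover score additivity
  and permutation invariance, management monotonicity, Wilson
  containment/symmetry against an independent closed form, and the
  reconstruction round-trip identity.

## Known limitations

* The default weight table is a documented stand-in; conclusions about real
  panels require study-calibrated weights.
* Per-nodule analysis only: multi-nodule patients, interobserver
  adjudication, extent-of-surgery decisions and cost analysis are out of
  scope.
* Reconstruction assumes the printed metrics derive from one common 2×2
  table per score; reports mixing margins across metrics (as the bundled
  pilot study does for the genomic score) yield empty joint solution sets by
  design.
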