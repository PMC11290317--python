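# Methods

## The test

A randomized trial is tested for selection-bias risk through the
heterogeneity it induces in a baseline-variable meta-analysis. Two
simulated comparator trials (SCTs) provide a homogeneous anchor; the
candidate trial is pooled with them and the I² point estimate of the
three-study fixed-effect model is read:

1. **SCT construction.** Draw `count` = 200 integers uniformly with
   replacement from [`lower`, `upper`] = [8, 80] (years of age), sort them
   ascending, and deal them into arms A and B by a permuted-block
   allocation sequence with block size 4 (each consecutive block a uniform
   draw from the six balanced arrangements of two A's and two B's). Each
   arm has N = 100 subjects; per-arm mean and sample SD (n − 1 denominator,
   the convention of trial reports and meta-analysis software) summarize
   the allocation.
2. **Confirmation.** Two SCTs are generated independently (fresh values
   and fresh allocation each) and pooled by fixed-effect inverse-variance
   meta-analysis of their arm mean differences; the pair is accepted when
   I² = 0 exactly, otherwise the whole pair is regenerated (capped at
   `max_regenerations` = 1000, attempts recorded).
3. **Testing.** The trial's effect — mean difference A − B with variance
   SD²_A/N_A + SD²_B/N_B — joins the two SCT effects. Q, df = 2, and
   I² = 100·max(0, (Q − df)/Q) are computed; I² > 0 % is a positive test
   (high selection-bias risk), I² = 0 % negative.

The positivity rule uses the *unrounded* I², i.e. positive ⇔ Q > df
strictly. Software that displays I² rounded to integer percent would call
0 < I² < 0.5 negative; a `round_display` flag emulates that convention,
off by default because the exact rule is the faithful reading of
"I² > 0 %".

**Assumptions.** The test inherits the premise that baseline variables
share none of the causes of outcome heterogeneity, so any baseline
heterogeneity signals randomization failure. It sees only reported
summaries: reporting or transcription errors in means/SDs are
indistinguishable from misallocation.

### Confirmation probability

Because the values are sorted before being dealt by balanced blocks, each
block contributes the difference of four neighbouring order statistics to
the arm-mean gap; |mean_A − mean_B| is then orders of magnitude smaller
than the reported two-sample standard error, so the two-study Q is ~10⁻³
against df = 1 and the pair confirms essentially always (simulated
frequency 1.0 over thousands of pairs). A chi-square null P(χ²₁ ≤ 1) ≈ 0.68
would describe *independent* (unsorted) allocation instead; one acceptance
test asserts that chi-square band to document the discrepancy and fails by
design. The regeneration loop in step 2 is therefore a guard, not a real
rejection sampler.

### SCT value range

The fixed default range (8, 80) is kept even when the tested trial's ages
lie elsewhere; a `trial_range` mode instead derives bounds from the trial's
mean ± 3·SD over both arms, rounded outward to integers, for trials whose
baseline variable lives on a different scale. Because the SCT arm *means*
cluster tightly at the range midpoint either way, the choice affects the
SCT weights, not the qualitative behaviour.

### Pair reuse

By default every trial gets a fresh, independently confirmed SCT pair,
seeded per trial from the run seed (a `SeedSequence` keyed by row index),
so per-trial results are reproducible in isolation from the recorded
`sct_seed`. A `shared_pair` mode builds one confirmed pair at `fit` time
and reuses it for the whole cohort; results then depend on a single draw,
which is cheaper and makes per-trial I² values directly comparable, at the
price of correlating all decisions with one anchor realization.

## Summary normalization

- mean(SD): used as reported.
- mean(SE): SD = SE·√N. These remain part of the main analysis — the mean
  itself was measured — and are not flagged as converted.
- median(min–max), n-dependent (Hozo): mean = (a + 2m + b)/4;
  SD = √(((a − 2m + b)²/4 + (b − a)²)/12) for n ≤ 15, (b − a)/4 for
  15 < n ≤ 70, (b − a)/6 for n > 70. All three branches are implemented;
  the thresholds (15, 70) are module constants.
- median(IQR) (Wan): mean = (q1 + m + q3)/3;
  SD = (q3 − q1)/(2·Φ⁻¹((0.75n − 0.125)/(n + 0.25))), Φ⁻¹ evaluated to
  full double precision (no table interpolation). A degenerate q1 = q3 is
  rejected because a zero SD violates the arm-summary contract.

Median-converted arms carry `converted = True`; the cohort driver excludes
such trials from the main analysis and adds them under
`include_converted`, mirroring the sensitivity-analysis design.

## Cohort auditing

Classification treats the I² test as reference and the RoB 2 rating as
index: (high, positive) → TP, (high, negative) → FP, (low, negative) → TN,
(low, positive) → FN. Trials rated "some concerns" overall, or without a
usable domain-1 rating, are tested but not tallied (counted and logged).
For multi-arm trials, `select_arm_pair` picks the pair maximizing the
two-sample z-statistic |mean_i − mean_j|/√(sd_i²/n_i + sd_j²/n_j), ties
broken by first occurrence; this runs at cohort-preparation time.

### Diagnostics

- FOR, literal: FN/(FN+TN).
- FOR, prevalence-adjusted: (1−Se)p/(Sp(1−p) + (1−Se)p) with p the
  prevalence rounded to `prevalence_rounding` = 1 decimal in percent. With
  the exact prevalence the two coincide algebraically (property-tested);
  after rounding they differ in the second decimal. Reports show both and
  flag a difference explicitly rather than choosing silently.
- FOR 95 % CI: logit (delta-method) interval on NPV = 1 − FOR with
  var(logit NPV) = (1−Sp)/(Sp·(TN+FP)) + Se/((1−Se)·(TP+FN)), bounds
  back-transformed and mapped to FOR. Undefined at boundary Se/Sp ∈ {0, 1};
  reports then degrade to the point estimates that remain defined.
- −LR = (1−Se)/Sp with log-method interval,
  var(ln −LR) = Se/((1−Se)·(TP+FN)) + (1−Sp)/(Sp·(TN+FP)).
- z = 1.959964 (the two-sided 95 % quantile at calculator precision).
- −LR interpretation bands are upper-closed: (0, 0.1] "highly likely",
  (0.1, 0.2] "moderately", (0.2, 0.5] "somewhat", (0.5, 1.0] "rarely
  likely" that a low-bias rating reflects truly low selection-bias risk,
  > 1 "adverse" (a low-bias rating makes high risk *more* likely).

The delta-method variance treats the positive/negative margins as fixed;
the coverage check in the test suite simulates under that design (fixed
margins, n = 1000) and sees nominal 95 % coverage within Monte-Carlo
tolerance plus a small allowance for the approximation.

## Synthetic cohorts

The generator emulates a cohort of appraised trials: per trial, two arms
of individual values drawn Normal(μ = 44, σ = 21) — matching the first two
moments of the SCTs' uniform(8, 80) so synthetic trials sit in the default
range — with arm sizes uniform on (20, 200). Misallocation is a mean shift
of arm A by δ·σ in a `biased_fraction` of trials (default 0.078, the
test-positive prevalence scale seen in practice). Labels are
truth-consistent with probability 1 − `label_noise`; a `domain1_missing`
fraction (default 0.28) gets no domain-1 rating, and `median_fraction`
degrades summaries to median(IQR) to exercise the conversion path. The
truth table is returned separately so the pipeline never sees it.

What the generator does **not** model: real RoB 2 rating behaviour (labels
here are noisy functions of the simulated truth, not of trial reporting),
variance-inflation forms of misallocation, non-normal or skewed baseline
variables, and correlated baseline variables within a trial. Passing tests
therefore demonstrate the machinery's statistical behaviour under a clean
mean-shift mechanism, not the field accuracy of any rating instrument.

## Problem sizes and numerical choices

The power-monotonicity check uses 500 trials per shift level over
δ ∈ {0, 0.1, 0.2, 0.5, 1.0}·σ with common random numbers across levels
(the same cohort draws, shifted), which couples the levels and leaves a
0.02 Monte-Carlo slack per adjacent comparison; block-arrangement
uniformity uses 6000 draws against 3 binomial SEs; pair-confirmation
frequency uses 2000 attempts. Pooling is validated against a brute-force
double-loop Q to 1e−10, and the adjusted-FOR identity on 10 000 random
tables to 1e−12. CSV round-trips write floats at 17 significant digits.

## Limitations

- The test's own false-positive rate under true randomization is not zero:
  sampling imbalance alone can push Q above df, and the FOR of a rating
  instrument is judged against the test, not against ground truth.
- Median conversions assume approximate symmetry (Hozo) or normality
  (Wan); heavily skewed baselines bias the converted SD and hence the
  trial's weight.
- With `shared_pair`, borderline trials' calls hinge on one anchor draw;
  fresh pairs average this out but make single-trial I² values
  non-comparable across trials.
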