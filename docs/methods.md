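# Methods

## The screening problem

The package targets case–control discrimination between surgically
treated degenerative cervical myelopathy (DCM) patients and screened
healthy controls, using two negatively oriented hand tests: the 10-s
grip-and-release repetition count (GRT, integer) and grip strength (kg,
0.5-kg instrument grid). "Diagnostic performance" throughout means this
case–control discrimination under resubstitution (cutoffs derived and
evaluated on the same cohort, no held-out set); it is an optimistic
estimate of prospective screening performance, as for any
Youden-optimized cutoff.

## Scoring and stratification

Each subject contributes one score per test: the minimum of the left and
right measurements (the more affected hand carries the diagnostic
signal). Analyses are stratified into eight cells — sex × closed age
bands [40, 59], [60, 69], [70, 79], [80, 89] — because both tests decline
with age and differ by sex. Age is taken as supplied, with no
date-of-measurement arithmetic. Records missing any measurement are
rejected wholesale (no imputation), mirroring how incomplete
participants are excluded from accuracy studies. Quantization
violations (grip off the 0.5-kg grid, fractional repetition counts) are
hard errors rather than silently rounded: they almost always indicate a
unit mistake (lb vs kg) or a corrupted export.

## Cutoff derivation

For each stratum and test, candidate thresholds are the distinct
observed values. Under the "abnormal if value ≤ cutoff" rule every
achievable ROC operating point occurs at an observed value, so
interpolated thresholds add nothing, and the selected cutoff is always
an attainable measurement. The cutoff maximizes Youden's
J = sensitivity + specificity − 1, computed in exact integer arithmetic
on confusion counts (J·n₁·n₀ = TP·n₀ + TN·n₁ − n₁·n₀), so ties are
detected without floating-point tolerance. When several thresholds tie
on J, the default rule takes the higher-sensitivity point — the largest
cutoff under this orientation — because a screening tool's purpose is to
avoid missed cases; a `tie_rule="specificity"` option takes the smallest
instead. The two tests' cutoffs are derived independently per stratum.

The empirical AUC is the Mann–Whitney statistic with ties weighted ½,
computed from midranks in O(n log n); it equals the trapezoidal area
under the empirical ROC staircase exactly (a property-tested identity).
The tie convention matters here because GRT is integer-valued with heavy
ties. Where specificity is exactly 1, LR+ is reported as an `inf`
sentinel (serialized as the string `"inf"` in text reports) rather than
a division error; an LR that is 0/0 is NaN and printed `NA`.

## The OR-combination rule

A subject screens positive when either test is abnormal (parallel
combination). With both component rules sharing the same cutoffs, the
positive set of the combined rule is the union of the component positive
sets, so per-stratum combined sensitivity ≥ each single-test sensitivity
and combined specificity ≤ each single-test specificity — an invariant
asserted on every evaluated cohort, not just sampled. Pooled "total"
metrics are computed from the elementwise sum of stratum confusion
tables (a single overall 2×2); averaging stratum-level proportions would
weight cells arbitrarily and is never done.

## Synthetic cohorts

The generator's default parameter set is the published per-stratum
n/mean/SD table of the tool's development cohort: 721 controls and 247
cases across the 16 (stratum, group) cells, e.g. male 60–69 controls
n = 62 with grip 35.5 ± 7.8 kg, female 80–89 cases n = 15 with grip
4.4 ± 4.0 kg. Each subject's latent (GRT, grip) pair is bivariate
normal with the cell's marginal moments and correlation ρ.

- **ρ (default 0.5, configurable).** The published tables report no
  within-subject correlation between the two tests, yet the combined
  rule's specificity depends on it directly (highly correlated tests
  produce overlapping false-positive sets; independent tests compound
  them). Both tests probe overlapping aspects of hand function, so a
  moderate positive correlation is the realistic middle ground; because
  the choice is consequential, ρ is a first-class parameter rather than
  a buried constant.
- **Modes.** `raw` emits the latent values untouched — continuous,
  occasionally negative — and is the mode for distributional checks: its
  moments and its empirical AUC converge to the normal-theory values,
  in particular AUC → Φ(|μ₀ − μ₁| / √(σ₀² + σ₁²)). `realistic` redraws
  any subject with a negative component until both are nonnegative,
  then rounds GRT to an integer and grip to the 0.5-kg grid, yielding
  records that pass full validation. Truncation is by resampling, not
  clamping: clamping would pile a point mass at zero and distort the
  ROC tie structure. For cells with non-negligible normal mass below
  zero (female 80–89 cases, grip 4.4 ± 4.0 kg: ~14 %), truncation
  necessarily raises the realized mean above the nominal one; this is
  documented behavior and asserted in the tests.
- **Laterality.** Only worse-hand minima were ever published, so
  simulating a left/right difference would invent structure; both hands
  are emitted equal to the drawn value. The worse-hand code path still
  executes (as the identity) on synthetic data.
- **Ages** are uniform integers within the band — the published tables
  give no within-band distribution, and nothing downstream uses age
  beyond band assignment.
- **Seeding.** A master seed spawns one independent substream per
  (stratum, group) cell via `numpy.random.SeedSequence`, so any cell's
  draw is reproducible in isolation and unaffected by other cells'
  sample sizes.

What passing tests on synthetic data do **not** show: real GRT/grip
distributions are skewed and integer-censored rather than truncated
normal, real left/right differences are informative, and the real
cases are surgical patients (a severe end of the disease spectrum).
Synthetic results validate the *machinery* — cutoff search, rule
combination, bookkeeping — not the clinical performance of the tool.

## Group comparison

Between-group differences use the two-sided Wilcoxon rank-sum test.
When both groups have n ≤ 10 the p-value comes from full enumeration of
all group assignments (exact even under ties); larger samples use the
normal approximation with midrank tie-corrected variance and continuity
correction, appropriate for heavily tied integer counts. If every value
in both groups is identical, p = 1 by convention. The 0.05 threshold is
report annotation only; no decision logic branches on it.

## Numerical and reporting conventions

- Proportions and likelihood ratios display at 2 decimals, means/SDs at
  1, using decimal half-up rounding (0.125 → 0.13) to match clinical
  table conventions; CSV/JSON outputs keep full precision.
- Metrics with zero denominators (a stratum with no cases or no
  controls) are NaN — flagged, never dropped, never defaulted.
- The CLI writes each run's resolved configuration and a structured log
  beside its outputs; logs carry no timestamps so a fixed-seed
  simulate → derive → evaluate pipeline is byte-identical across runs.
- Exit codes: 0 success, 2 validation/configuration error,
  3 insufficient data.

## Problem sizes

Stochastic checks use sizes at which Monte-Carlo error is far below the
assertion tolerance: 2 × 10⁵ per group for AUC recovery (AUC standard
error ≈ 4 × 10⁻⁴, two orders below the 2-decimal reporting grid),
10⁵ for moment recovery (asserted within 3 standard errors), and 10³
random instances for the exact-identity properties (Youden = brute
force, trapezoid = pair counting), which hold to machine precision.

## Known limitations

- Resubstitution evaluation overstates prospective performance; a
  train/test split is available but off by default to mirror the
  development analysis.
- One published single-test row (grip, male 40–59) prints
  sensitivity/specificity cells inconsistent with its own likelihood
  ratios; its LR values are excluded from arithmetic cross-checks.
  Pooled-total LRs and the combined-rule LR+ values are computed from
  unpublished raw counts and cannot be exactly recovered from the
  rounded published proportions.
- The published overall combined-rule figures appear in two versions
  (an abstract-level 88.2 %/78.1 % and a pooled-table 0.91/0.73); the
  pooled-counts computation is the only one whose derivation is
  defined, and it is the one implemented.
- Cutoffs for the 80–89 bands rest on very small case counts (12 male,
  15 female) and are correspondingly unstable under resampling.
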