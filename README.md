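# dcmscreen

Degenerative cervical myelopathy (DCM) — spinal cord dysfunction from
degenerative compression of the cervical spine — is routinely diagnosed
late because its early hand symptoms are easy to miss in primary care.
Two bedside tests pick them up cheaply: the **10-s grip and release test
(GRT)**, the number of complete hand open–close cycles in 10 seconds
(myelopathic clumsiness lowers it), and **grip strength** in kg (cord
compression weakens it). Both decline with age and differ by sex, so a
single cutoff misleads.

`dcmscreen` implements, as a tested reusable pipeline, the construction
and evaluation of a stratified two-test screening rule for DCM:

- **Worse-hand scoring** — each subject's score per test is the lower of
  the left/right measurements.
- **Stratified Youden cutoffs** — within each of eight sex × age cells
  (M/F × 40–59, 60–69, 70–79, 80–89 years), the cutoff *c* for each test
  maximizes Youden's index *J = sensitivity + specificity − 1* over the
  empirical ROC curve, under the negative orientation "value ≤ *c* ⇒
  abnormal". The empirical AUC is the Mann–Whitney statistic
  *P(case < control) + ½ P(case = control)*.
- **OR-combination rule** — the screen is positive when *either* test is
  abnormal; this raises sensitivity and lowers specificity relative to
  each component test, the right trade-off for screening.
- **Performance evaluation** — per-stratum and pooled 2×2 tables with
  sensitivity, specificity, LR+ = sens/(1 − spec) and
  LR− = (1 − sens)/spec, with the DCM (surgical) group as the
  condition-positive class.
- **Synthetic cohorts** — no individual-level data were ever deposited
  for this tool, only per-stratum n/mean/SD summaries. The generator
  draws correlated (GRT, grip) pairs from bivariate normals at exactly
  those published moments (721 controls + 247 cases by default), with
  optional zero-truncation and instrument rounding, so every stage runs
  end to end without patient data.

Intended users: biostatisticians reproducing or extending stratified
diagnostic-accuracy analyses, and developers validating screening-rule
implementations against published summary tables.

## Worked example

Simulate a cohort at the published stratum statistics, derive cutoffs,
and screen one subject:

```bash
$ dcmscreen simulate --seed 1 --out out/sim
wrote out/sim/cohort.csv (968 subjects: 247 dcm, 721 control)

$ dcmscreen derive --cohort out/sim/cohort.csv --out out/derive
# ...descriptive table, then the per-test derivation report:
Sex     Age (y)  Test     AUC  Cutoff  Sens  Spec     LR+     LR-
-----------------------------------------------------------------
female  40-59    grt     0.83      21  0.86  0.68    2.70    0.20
female  40-59    grip    0.88    22.5  0.95  0.68    2.99    0.07
female  60-69    grt     0.92      16  0.83  0.89    7.33    0.19
...
```

Each row is one test in one stratum: the empirical AUC, the
J-maximizing cutoff (an attainable measurement value — an integer count
or a 0.5-kg grip value), and the resubstitution sensitivity/specificity
and likelihood ratios at that cutoff. For example, female 60–69 GRT:
AUC 0.92, cutoff 16 repetitions, sensitivity 0.83 and specificity 0.89,
so a positive GRT multiplies the odds of DCM by 7.33.

Screening a single subject against the shipped published cutoff table:

```bash
$ dcmscreen classify --sex male --age 72 \
    --grt-left 16 --grt-right 14 --grip-left 22.0 --grip-right 20.5
stratum: male 70-79
GRT min 14 (cutoff 15): abnormal
grip min 20.5 kg (cutoff 21 kg): abnormal
screen result: POSITIVE
Note: this is a screening support tool only; a positive result calls for specialist referral, not a diagnosis.
```

The worse hand (GRT 14, grip 20.5 kg) is at or below both male 70–79
cutoffs, so the screen is positive. `dcmscreen evaluate` applies any
cutoff table to a cohort and reports per-stratum plus pooled
performance for GRT alone, grip alone, and the combined rule.

The same operations are available as library functions
(`dcmscreen.youden_cutoff`, `derive_tool`, `evaluate_rule`,
`simulate_study`, ...).

## Layout

- `src/dcmscreen/cohort.py` — domain types, validation, worse-hand scoring, CSV I/O
- `src/dcmscreen/synthetic.py` — bivariate-normal cohort generator
- `src/dcmscreen/roc.py` — empirical AUC, ROC staircases, Youden cutoffs
- `src/dcmscreen/rule.py` — cutoff tables, OR rule, performance evaluation
- `src/dcmscreen/stats.py` — stratum summaries, Wilcoxon rank-sum test
- `src/dcmscreen/cli.py`, `report.py` — command-line pipeline and report formatting
- `src/dcmscreen/reference.py` — published stratum statistics, cutoffs and performance
- `docs/methods.md` — model, assumptions, numerical choices, limitations
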