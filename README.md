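# habitrace

Analysis tools for visual habituation experiments in larval zebrafish:
repeated **loom** (dark expanding disc), **checkerboard loom** (expanding
isoluminant checkerboard — moving edges without a luminance change), and
**dim** (whole-field darkening) stimuli, paired with either free-swimming
escape behavior or whole-brain calcium imaging. The package is aimed at
systems-neuroscience groups who want a tested, reusable version of this
analysis chain, and at anyone who needs its statistical pieces — a
rank-based longitudinal habituation test, exact small-sample nonparametric
comparisons, or robust exponential-decay fitting — outside this exact
experiment.

## What it computes

**Behavior.** Per-second tracking distances are classified as drift
(< 0.5 mm/s), scoots (0.5–30 mm/s) or escapes (> 30 mm/s). The escape
probability per stimulus is the fraction of fish with an escape bin inside
the 5 s expansion window. Habituation within a group is tested with the
rank-based ANOVA-type statistic (ATS) for a one-group longitudinal design
(pooled mid-ranks, box-type degrees-of-freedom adjustment), groups are
compared with exact Mann–Whitney *U* tests under Bonferroni correction,
and habituation curves are summarized by a one-phase decay
*p(k) = Y₀·e^(−Kk)* (plateau 0, stimuli 1–20) plus a linear tail fit
(stimuli 21–30).

**Calcium imaging.** Fluorescence traces (2 Hz, one per ROI) are z-scored,
regressed on kernel-convolved stimulus regressors, and thresholded at the
pooled median + 2 SD of r² to find responsive ROIs. Per-stimulus response
size is the window maximum minus the pre-stimulus baseline. Downstream:

- *functional clustering* — over-clustered k-means (k = 10, 20 replicates)
  with four consistency criteria (member correlation > 0.5, ≥ 100 ROIs,
  ≥ 75% of fish, ≤ 33% from any single fish) and correlation-based merging;
- *component sensitivity* — classification of each ROI as dim-, checker-,
  dual- or non-sensitive from its responses to flanking component stimuli;
- *habituation rate* — a robust least-absolute-residuals fit of
  **f(x) = a + b·e^(−cx)** to the ten loom responses of every ROI
  (adjusted r² > 0.5 and SSE < 20 to accept), with per-fish class medians
  of *c* compared by a Friedman test (exact by enumeration up to 8 fish).

**Synthetic cohorts.** A first-class generator produces seeded multi-fish
cohorts with known sensitivity classes, response amplitudes, habituation
constants, and escape dynamics, emulating source-extracted calcium traces
(kernel-convolved transients, Gaussian noise, exponentially habituating
amplitudes) and 1 s-binned tracking output. Every analysis above is
validated against this ground truth.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from habitrace import CohortConfig, generate_cohort, run_experiment3

cfg = CohortConfig(n_fish=6, rois_per_fish=300)
cohort = generate_cohort(cfg, seed=7)          # component protocol: d,c,d,c + 10 looms + d,c,d,c
stats, table = run_experiment3(cohort)

print(f"responsive ROIs: {len(table)} / {len(cohort.rois)}")
print(table["label"].value_counts().to_string())
acc = table[table["accepted"] == True]
print(f"accepted decay fits: {len(acc)}")
print("median c by class:")
print(acc.groupby("label")["c"].median().round(3).to_string())
print(f"Friedman: chi2 = {stats.friedman.statistic:.3f}, "
      f"p = {stats.friedman.p_value:.4f} ({stats.friedman.n_blocks} fish)")
```

prints

```
responsive ROIs: 247 / 1800
label
checker    136
both        62
dim         49
accepted decay fits: 247
median c by class:
label
both       0.804
checker    0.851
dim        0.777
Friedman: chi2 = 1.333, p = 0.5705 (6 fish)
```

247 of 1800 ROIs pass the median + 2 SD responsiveness threshold, split
into checkerboard-, dual- and dim-sensitive classes (checker most common,
dim rarest, matching the generator's mixture). All pass the decay
goodness-of-fit filter here, and the three classes habituate at
statistically indistinguishable rates (Friedman p = 0.57) — as expected,
since this cohort draws every ROI's *c* from the same distribution
regardless of class.

A command-line interface mirrors the library:

```sh
habitrace simulate --seed 1 --n-fish 6 --rois-per-fish 300 --out cohort/
habitrace habituate --traces cohort/traces.csv --rois cohort/rois.csv \
    --train cohort/train.json --out results/
habitrace run-all --config config.yaml --out results/
```

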