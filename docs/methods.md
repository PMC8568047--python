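# Methods

`habitrace` implements the analysis chain of a larval-zebrafish visual
habituation study: repeated loom, checkerboard-loom, and dimming stimuli are
presented while either free-swimming behavior or whole-brain calcium
activity is recorded, and the package quantifies which units respond to
which stimulus component and how quickly those responses decay with
repetition. Because raw recordings are not part of the package, every
analysis is exercised end to end on synthetic cohorts whose ground truth
(sensitivity class, response amplitude, habituation rate, escape dynamics)
is known exactly.

## Stimulus model

A stimulus event expands hyperbolically from a point to its maximum over
`expand_s` (default 5 s) and fades back linearly over `fade_s` (default
15 s). The rise follows the standard looming-angle profile
θ(t) = 2·atan(r / (v·(t_max − t))), normalized to [0, 1]; the ratio r/v is
fixed so the initial angle is 1% of the capped maximum (99% of a full
half-field), which pins the curve with no free parameter. Protocols:

| protocol | events | ISI |
|---|---|---|
| `behavior_{loom,checker,dim}` | 20 of one kind, then 10 looms | random in {20, 25, 30, 35} s |
| `imaging1_{loom,checker,dim}` | 10 of one kind, then 5 looms | 20 s |
| `imaging2_sequence` | dim, checker, loom ×2 | 60 s spacing, 5 min mid-break |
| `imaging3_component` | d, c, d, c — 10 looms — d, c, d, c | 20 s |

Imaging trains start with 30 s of baseline, behavioral trains with 5 min.
Regressors mark each event's expansion period and are convolved with a
causal exponential kernel exp(−t/τ); τ defaults to 3.5 s, a first-order
approximation of nuclear GCaMP6s decay at 2 Hz sampling. The expansion
period (not the fade) drives the regressor because evoked responses align
to expansion onset.

## Synthetic cohorts

Each ROI carries a sensitivity class: `dim`, `checker`, `both`, or `none`.
Looms drive every responsive class (their luminance component recruits
dim-sensitive units, their moving edges recruit checkerboard-sensitive
ones); there is deliberately no loom-specific component, so loom responses
are exactly the sum of the component responses. The k-th same-kind
presentation evokes a transient of amplitude A·exp(−c·(k−1)) (A default
3 z, c ~ U(0.2, 1.2) per ROI), convolved with the calcium kernel, plus
i.i.d. Gaussian noise (default SD 1). Traces are later z-scored, so no
photobleaching drift or offset is simulated by default.

Defaults are one cohort's study conditions: 11 fish, 500 ROIs per fish,
class mixture 2% dim / 8% checker / 4% both / 86% none. The mixture makes
responsive ROIs a clear minority, with checkerboard-sensitive units about
four times as common as dim-sensitive ones and dual-sensitive units in
between — the relative abundances whole-brain recordings show. The minority
structure matters statistically: the responsive threshold is the pooled
median + 2 SD of r², and when responders approach half the population the
mixture variance pushes that threshold into the responders' own
distribution, capping attainable sensitivity near 50% regardless of effect
size. Clustering demonstrations use a richer explicit mixture
(6/13/7/74%) because the ≥100-member cluster criterion needs enough
selected ROIs per class once k-means splits classes.

Region labels are drawn from class-specific priors (dual-sensitive units
concentrated in tectum; dim-sensitive in habenula/thalamus/tectum) — these
encode qualitative anatomy as configurable priors, not assertions about any
particular brain.

Behavioral records are per-second distances: an 80/20 drift/scoot baseline
mixture (|N(0.1, 0.1)| mm/s and U(0.5, 5) mm/s) with escape bins
(U(35, 80) mm/s) placed inside the response window on per-stimulus
Bernoulli draws. The loom escape model habituates as
p_k = p₀·exp(−λ(k−1)) (defaults p₀ = 0.8, λ = 0.25); checkerboards use a
constant rate, dims a near-zero one.

What the generator does **not** emulate: overlapping-source demixing
errors, motion artifacts, correlated (shared) noise across ROIs, inter-fish
amplitude variability (available via `amplitude_jitter` but off by
default), and visual-field position effects. Passing recovery tests
therefore show the analysis is correct under its own assumptions, not that
those assumptions hold for any particular recording.

## Responsiveness selection

Traces are standardized per ROI over the full record using the sample SD
(n−1). "Pooling" is read as assembling all fish into one matrix before
thresholding, not as sharing one mean/SD across ROIs — cross-ROI pooled
standardization would leave ROI-specific offsets that break regression
comparability (the alternative remains available via
`zscore_pooled(per_roi=False)`).

Each z trace is regressed (OLS with intercept) on a stimulus regressor over
a fit range spanning the relevant presentations; r² with a single regressor
equals the squared Pearson correlation. For habituating responses a single
flat regressor is systematically mis-specified — with amplitudes decaying
at c ≈ 0.7 the correlation ceiling is about 0.65 even without noise — so
the component pipeline regresses on one kernel-convolved column per
presentation (`event_design`), which absorbs arbitrary per-presentation
amplitudes and yields uniformly high r² for true responders of every class.

ROIs pass when r² strictly exceeds median + 2·SD of the pooled r²
distribution. The threshold is a realization of each dataset, not a
constant. Per-stimulus response size is the window maximum (expansion +
fade) minus the mean of the preceding 5 s baseline. Group curves average
ROIs within fish before averaging fish, so ROI-rich fish carry no extra
weight.

## Component classification

An ROI's evidence is its mean baseline-subtracted max response to the four
flanking dims and the four flanking checkerboards. The maximum of a
40-sample noise window is itself positive (≈ 2.1× the noise SD by extreme
value statistics), so raw evidence cannot be compared against a 1 z
threshold. The pipeline therefore subtracts each ROI's expected
noise-window maximum — Blom's order-statistic approximation evaluated with
a robust noise SD from the median absolute first difference of the trace
(successive-difference noise estimation, valid because transients are slow
at 2 Hz) — and applies the threshold (default θ = 1 z, strict) to the
excess. Dim excess above θ → `dim`, checker excess → `checker`, both →
`both`, neither → `none`. θ's effect is covered by sensitivity tests; the
debiasing makes the default transfer across noise levels.

## Habituation-rate fitting

For each classified ROI the ten loom max responses are fit with
f(x) = a + b·exp(−c·x), x the 1-based loom index (the origin choice only
rescales b; c, the compared quantity, is origin-invariant). The fit
minimizes the sum of absolute residuals (LAR) to limit single-presentation
outliers, via iteratively reweighted least squares: weights
1/max(|residual|, 1e−6), the profiled (a, b) solved in closed form for each
c, c found by bounded search on [0, 10], multi-started at
c₀ ∈ {0.05, 0.3, 0.7, 1.5}, best start by L1 objective. Iterations cap at
200 with a 1e−9 parameter tolerance; because IRLS on an L1 objective
converges only linearly and often orbits the non-differentiable optimum,
the loop also stops when the objective improves by less than 1e−5
relatively per sweep — without this, well-fit ROIs are misreported as
non-converged. A vectorized batch fitter (golden-section in c across all
ROIs simultaneously) implements the identical scheme and is
cross-checked against the scalar path in tests.

Fits are accepted when adjusted r² > 0.5 (n = 10, p = 3) and SSE < 20 (z²
units); non-converged fits are reported unaccepted. Accepted ROIs' c values
are reduced to per-fish class medians; fish missing any class are dropped
from the block design. The Friedman test compares classes within fish:
within-block mid-ranks with tie correction, exact p by full (k!)^b
enumeration up to 8 blocks, chi-square (k−1 df) beyond.

## Behavioral statistics

Speed classes: drift < 0.5 mm/s, scoots 0.5–30 mm/s (closed interval,
matching the printed range), escapes > 30 mm/s. Fish with no escape
anywhere are excluded. An escape is attributed to a stimulus when any bin
in [onset, onset + 5 s) exceeds 30 mm/s — the expansion period, since no
explicit attribution window is standard; windows reaching the next onset
are truncated with a warning.

Habituation within a group is tested on per-fish binary responses at three
time points (first and last of the initial block, first loom probe) with
the rank-based ANOVA-type statistic for longitudinal one-group designs:
pooled mid-ranks, relative effects p̂_t = (R̄_t − ½)/N, statistic
A = n·p̂'Cp̂ / tr(CV) referred to F(f̂, f̂₀) with box-type degrees of
freedom f̂ = tr(CV)²/tr(CVCV) and f̂₀ = (n−1)·tr(CV)²/Σ(CV)²_tt. Simulated
type-I error is 0.03–0.07 at α = 0.05 for binary and continuous
exchangeable nulls at n = 20. When every subject shows the identical
nonzero pattern the rank covariance is singular while the effect is
maximal; this degenerate case returns p = 0 (all-constant data returns
p = 1).

Between-train comparisons use two-sided Mann-Whitney U: full-enumeration
exact p (valid under ties, two-sided as twice the smaller tail) for
combined n ≤ 20, tie-corrected normal approximation beyond, with Bonferroni
correction p·m capped at 1. Escape curves are summarized by a one-phase
decay Y0·exp(−K·k) with plateau fixed at 0 on stimuli 1–20 (least squares,
multi-start over K) and an ordinary linear regression on stimuli 21–30.

## Clustering

Responsive z traces are over-clustered with Euclidean k-means (k = 10,
best of 20 seeded replicates) so idiosyncratic profiles can be discarded by
validation rather than absorbed. A cluster is retained when (1) members
correlate > 0.5 with the cluster mean — low-correlation members are pruned
first by default; a strict mode rejects the whole cluster instead — and the
survivors number (2) ≥ 100, come from (3) ≥ 75% of fish, with (4) no fish
contributing > 33%. "Represented in" a fish means at least one member ROI.

Retained clusters are merged when their mean traces correlate above a
threshold, by transitive closure (order-independent), with member-weighted
merged means. Because every responsive class responds to looms, cross-class
cluster means already correlate at ≈ 0.76–0.81 on kernel-convolved traces;
the default threshold is therefore 0.9, between that floor and the ≥ 0.95
correlations of same-class splinters. On three-class synthetic cohorts the
chain (select → cluster → validate → merge) ends at exactly three clusters
across seeds, with no loom-specific cluster — loom responses decompose into
the dim and checker components by construction.

Regional composition divides responsive by total ROI counts per region
within each fish, averages across fish (fish with no ROIs in a region are
omitted from that region's average), and normalizes the three class shares
to sum to 1 per region.

## Validation experiments and problem sizes

`habitrace.experiments` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) regenerates every quantity from scratch:

- decay recovery: 500 ROIs (2 fish), amplitude 3, trace noise 0.5 —
  median relative error of accepted ĉ (observed ≈ 9%);
- robustness: 1000 ROIs, +5 z at one random loom each (10% of points) —
  LAR vs plain least squares (≈ 10% vs ≈ 47%);
- calibration: 1000 exchangeable-null replicates per test;
- oracle equivalence: enumeration oracles for Friedman (4 blocks),
  Mann-Whitney (n = 9), and the squared-correlation identity;
- pipeline recovery: the default 11 × 500 cohort — selection
  sensitivity/specificity and class accuracy;
- headline: 50 equal-c cohorts (11 fish × 300 ROIs) for the non-rejection
  rate, 20 cohorts with class c = (0.2, 0.8, 0.8) for power;
- cluster rules: eight boundary fixtures;
- behavior: 25 habituating-loom and 25 flat-checkerboard cohorts of 24
  fish.

These sizes estimate each quantity stably in a few minutes on one CPU;
the headline block dominates (≈ 5 min).

## Known limitations

- The component-classification rule is a single threshold on debiased mean
  max responses; graded or probabilistic class membership is out of scope.
- The ATS is implemented for the one-group, T-time-point design only (no
  between-group factors).
- Exact Friedman enumeration grows as (k!)^b and is capped at 8 blocks.
- The LAR fit bounds c to [0, 10]; truly non-decaying ROIs (c = 0) sit on
  the boundary and their b is weakly identified.
- Atlas registration is replaced by categorical region labels carried in
  the data model; no spatial statistics are computed.
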