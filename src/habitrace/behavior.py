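"""Escape-behavior analysis: movement classes, escape curves, and statistics.

Free-swimming larvae are tracked at 1 s resolution; each bin's speed is
classified as drift (< 0.5 mm/s), scoot (0.5-30 mm/s) or escape
(> 30 mm/s). The per-stimulus escape probability is the fraction of fish
with at least one escape bin inside the stimulus response window (default:
the 5 s expansion period).

Habituation within a group is tested with a rank-based ANOVA-type statistic
(ATS) for a one-group longitudinal design (the nparLD LD-F1 family):
relative treatment effects are estimated from pooled mid-ranks and the ATS
is referred to an F distribution with box-type degrees-of-freedom
adjustment. Groups are compared with Mann-Whitney U tests under Bonferroni
correction. Habituation curves are summarized by a one-phase exponential
decay (plateau fixed at 0) over stimuli 1-20 and an ordinary linear
regression over stimuli 21-30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .stimulus import StimulusTrain
from .synthetic import BehaviorRecord

__all__ = [
    "EscapeCurve",
    "DecayCurveFit",
    "AtsResult",
    "classify_movement",
    "filter_fish",
    "escape_probability",
    "escape_matrix",
    "test_habituation",
    "mann_whitney_u",
    "fit_escape_decay",
]

DRIFT_MAX_MM_S = 0.5
ESCAPE_MIN_MM_S = 30.0


@dataclass(frozen=True)
class EscapeCurve:
    """Per-stimulus escape probabilities and the number of fish behind them."""

    p: np.ndarray  # p_k for k = 1..n_stimuli
    n_fish: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("escape probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", arr)

    def __len__(self) -> int:
        return len(self.p)


@dataclass(frozen=True)
class DecayCurveFit:
    """One-phase decay over stimuli 1-20 plus a linear tail fit over 21-30.

    The decay model is p_k = Y0 * exp(-K * k) with plateau fixed at zero.
    ``identifiable`` is False when the curve carries no decay information
    (e.g. all-zero responses), in which case K is NaN.
    """

    Y0: float
    K: float
    slope: float
    intercept: float
    identifiable: bool = True


@dataclass(frozen=True)
class AtsResult:
    """Rank-based ANOVA-type statistic for a longitudinal one-group design."""

    statistic: float
    df: float
    p_value: float


def classify_movement(speed_mm_s: float) -> str:
    """Classify a 1 s speed bin as 'drift', 'scoot' or 'escape'.

    Drift is strictly below 0.5 mm/s; scoots span the closed interval
    0.5-30 mm/s; escapes are strictly above 30 mm/s.
    """
    if speed_mm_s < 0:
        raise ValueError(f"speed must be >= 0, got {speed_mm_s}")
    if speed_mm_s < DRIFT_MAX_MM_S:
        return "drift"
    if speed_mm_s <= ESCAPE_MIN_MM_S:
        return "scoot"
    return "escape"


def filter_fish(records: list[BehaviorRecord]) -> list[BehaviorRecord]:
    """Drop fish with no escape-classified bin anywhere in the record.

    Mirrors the exclusion of untracked or never-escaping fish. Returns the
    retained records; an empty result is returned as an empty list (callers
    must handle the no-fish case explicitly).
    """
    if not records:
        raise ValueError("no behavior records provided")
    return [r for r in records if np.any(r.bins_mm > ESCAPE_MIN_MM_S)]


def _escape_bins(record: BehaviorRecord) -> np.ndarray:
    return record.bins_mm > ESCAPE_MIN_MM_S


def escape_matrix(
    records: list[BehaviorRecord],
    train: StimulusTrain,
    window_s: float | None = None,
) -> np.ndarray:
    """Binary fish x stimulus matrix: did fish i escape to stimulus k?

    An escape is attributed to stimulus k when at least one bin in
    [onset_k, onset_k + window_s) exceeds 30 mm/s. The default window is
    each event's expansion period. Windows reaching past the next onset are
    truncated with a warning.
    """
    n_fish = len(records)
    n_stim = len(train.events)
    out = np.zeros((n_fish, n_stim), dtype=bool)
    esc = [_escape_bins(r) for r in records]
    onsets = [ev.onset_s for ev in train.events]
    for k, ev in enumerate(train.events):
        win = ev.expand_s if window_s is None else window_s
        end = ev.onset_s + win
        if k + 1 < n_stim and end > onsets[k + 1]:
            warnings.warn(
                f"response window for stimulus {k + 1} overlaps the next onset; truncating",
                stacklevel=2,
            )
            end = onsets[k + 1]
        lo = int(np.floor(ev.onset_s))
        hi = int(np.ceil(end))
        for i, e in enumerate(esc):
            out[i, k] = bool(np.any(e[lo : min(hi, len(e))]))
    return out


def escape_probability(
    records: list[BehaviorRecord],
    train: StimulusTrain,
    window_s: float | None = None,
) -> EscapeCurve:
    """Per-stimulus escape probability: fraction of fish escaping to each stimulus."""
    if not records:
        raise ValueError("no behavior records provided")
    mat = escape_matrix(records, train, window_s=window_s)
    return EscapeCurve(p=mat.mean(axis=0), n_fish=len(records))


def test_habituation(*timepoints: np.ndarray) -> AtsResult:
    """Rank-based ATS for repeated measures of the same fish over time points.

    Accepts two or more same-length per-fish response vectors (binary or
    continuous), one per time point. All observations are pooled and
    mid-ranked; relative treatment effects p_t = (mean rank_t - 1/2) / N are
    contrasted with the centering matrix, and the ANOVA-type statistic

        A = n * p' C p / tr(C V)

    (C the T x T centering matrix, V the scaled empirical covariance of the
    per-fish rank vectors) is referred to F(f, f0) with box-type adjusted
    degrees of freedom f = tr(CV)^2 / tr(CVCV) and
    f0 = (n - 1) * tr(CV)^2 / sum_t (CV)_tt^2.

    Identical values everywhere give statistic 0 and p = 1 by convention.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least two time points")
    data = np.column_stack([np.asarray(t, dtype=float) for t in timepoints])
    n, T = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(data) == 0:
        return AtsResult(statistic=0.0, df=float(T - 1), p_value=1.0)

    N = n * T
    ranks = stats.rankdata(data.ravel()).reshape(n, T)  # pooled mid-ranks
    rbar = ranks.mean(axis=0)
    p_hat = (rbar - 0.5) / N
    C = np.eye(T) - np.full((T, T), 1.0 / T)
    S = np.cov(ranks, rowvar=False, ddof=1)  # T x T covariance of rank vectors
    V = S / N**2
    CV = C @ V
    tr_cv = np.trace(CV)
    effect = float(p_hat @ C @ p_hat)
    if tr_cv <= 0:
        # zero between-subject rank variance: either no effect at all, or a
        # perfectly consistent time effect in every subject
        if effect > 1e-15:
            return AtsResult(statistic=np.inf, df=float(T - 1), p_value=0.0)
        return AtsResult(statistic=0.0, df=float(T - 1), p_value=1.0)
    statistic = float(n * effect / tr_cv)
    f_hat = float(tr_cv**2 / np.trace(CV @ CV))
    diag_sq = float(np.sum(np.diag(CV) ** 2))
    f0_hat = float((n - 1) * tr_cv**2 / diag_sq) if diag_sq > 0 else np.inf
    p_value = float(stats.f.sf(statistic, f_hat, f0_hat))
    return AtsResult(statistic=statistic, df=f_hat, p_value=p_value)


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, n_comparisons: int = 1
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with Bonferroni correction.

    Exact p for combined n <= 20 (full enumeration of group assignments,
    valid under ties); tie-corrected normal approximation otherwise.
    Returns (U, p_raw, p_bonferroni).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    n_tot = len(x) + len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant samples: no evidence either way
        u = float(len(x) * len(y) / 2)
        return u, 1.0, 1.0
    if n_tot <= 20:
        has_ties = len(np.unique(np.concatenate([x, y]))) < n_tot
        if has_ties:
            # enumeration via permutation with enough resamples to be exact
            from math import comb

            method = stats.PermutationMethod(n_resamples=comb(n_tot, len(x)) + 1)
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p_raw = float(res.pvalue)
    return float(res.statistic), p_raw, min(1.0, p_raw * n_comparisons)


_K_STARTS = (0.01, 0.1, 0.5, 1.0)


def fit_escape_decay(
    curve: EscapeCurve,
    decay_range: tuple[int, int] = (1, 20),
    linear_range: tuple[int, int] = (21, 30),
) -> DecayCurveFit:
    """Fit p_k = Y0 exp(-K k) on the first block and a line on the tail block.

    Stimulus indices are 1-based and the ranges inclusive. The decay is a
    least-squares fit with plateau fixed at zero, multi-started over K in
    {0.01, 0.1, 0.5, 1}. An all-zero first block yields Y0 = 0 with K
    flagged not identifiable.
    """
    p = np.asarray(curve.p, dtype=float)
    lo, hi = decay_range
    if hi - lo + 1 < 4:
        raise ValueError("need at least 4 points in the decay range")
    k = np.arange(lo, hi + 1, dtype=float)
    y = p[lo - 1 : hi]
    if len(y) != len(k):
        raise ValueError("curve shorter than the requested decay range")

    llo, lhi = linear_range
    if lhi <= len(p) and lhi - llo + 1 >= 4:
        kx = np.arange(llo, lhi + 1, dtype=float)
        lin = stats.linregress(kx, p[llo - 1 : lhi])
        slope, intercept = float(lin.slope), float(lin.intercept)
    else:
        slope, intercept = np.nan, np.nan

    if np.all(y == 0):
        return DecayCurveFit(Y0=0.0, K=np.nan, slope=slope, intercept=intercept,
                             identifiable=False)

    def model(kk, y0, kdec):
        return y0 * np.exp(-kdec * kk)

    best = None
    for k0 in _K_STARTS:
        y0_init = float(y[0] * np.exp(k0 * k[0]))
        try:
            popt, _ = optimize.curve_fit(
                model, k, y, p0=[max(y0_init, 1e-6), k0],
                bounds=([0.0, 0.0], [np.inf, 10.0]), maxfev=10000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(k, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return DecayCurveFit(Y0=np.nan, K=np.nan, slope=slope, intercept=intercept,
                             identifiable=False)
    y0_fit, k_fit = best[1]
    return DecayCurveFit(Y0=float(y0_fit), K=float(k_fit), slope=slope,
                         intercept=intercept)
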