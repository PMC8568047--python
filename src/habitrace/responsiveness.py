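"""Responsive-ROI selection by regression against a stimulus regressor.

Traces are standardized per ROI over the full recording (z-scored). Each
z trace is regressed on a stimulus regressor over a fit range covering the
relevant stimuli, and the coefficient of determination r² is kept. ROIs
whose r² exceeds the pooled median + 2 SD are flagged responsive; the
threshold is a realization of each dataset, not a fixed constant.

Per-stimulus response size is the baseline-subtracted maximum: the peak z
value inside the stimulus window (expansion + fade) minus the mean z over
the preceding baseline (default 5 s). Group-level curves are two-stage
means: ROIs are averaged within fish before fish are averaged within group,
so fish with many ROIs do not dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import Regressor, StimulusEvent, StimulusTrain

__all__ = [
    "ResponsivenessResult",
    "zscore_trace",
    "zscore_pooled",
    "regress_roi",
    "regress_design",
    "event_design",
    "select_responsive",
    "max_response",
    "max_response_matrix",
    "noise_sd_estimate",
    "expected_noise_max",
    "group_mean_responses",
    "fit_range_for_events",
]


@dataclass(frozen=True)
class ResponsivenessResult:
    """Per-ROI r² values, the selection threshold, and responsive flags."""

    r2: pd.Series  # index roi_id
    threshold: float
    responsive: pd.Series  # boolean, same index

    @property
    def n_responsive(self) -> int:
        return int(self.responsive.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r2": self.r2, "responsive": self.responsive})


def zscore_trace(raw: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize one trace to zero mean, unit variance over the full record.

    Uses the sample standard deviation (n-1) by default. A constant trace
    cannot be standardized and raises; callers exclude such ROIs upstream.
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant trace cannot be z-scored")
    return (raw - raw.mean()) / sd


def zscore_pooled(traces: pd.DataFrame, per_roi: bool = True, ddof: int = 1) -> pd.DataFrame:
    """Standardize a ROI x sample trace matrix.

    ``per_roi=True`` (default) standardizes each row over its own record.
    ``per_roi=False`` standardizes with the grand mean and SD pooled across
    the whole matrix, preserving between-ROI offset/scale differences.
    Constant rows are dropped with a warning in per-ROI mode.
    """
    mat = traces.to_numpy(dtype=float)
    if per_roi:
        sd = mat.std(axis=1, ddof=ddof)
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} constant trace(s)", stacklevel=2
            )
        mat = mat[keep]
        z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, ddof=ddof, keepdims=True)
        return pd.DataFrame(z, index=traces.index[keep], columns=traces.columns)
    mu, sd = mat.mean(), mat.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant trace matrix cannot be z-scored")
    return pd.DataFrame((mat - mu) / sd, index=traces.index, columns=traces.columns)


def fit_range_for_events(
    train: StimulusTrain,
    event_indices: list[int],
    rate_hz: float,
    pad_s: float = 0.0,
) -> np.ndarray:
    """Sample indices spanning the selected events (0-based event indices).

    The range runs from the earliest selected onset (minus ``pad_s``) to the
    latest selected event's end (plus ``pad_s``), as one contiguous block
    per selected event. Used to restrict regression to a stimulus span, e.g.
    the first 10 stimuli, or the four flanking component stimuli on each
    side of the loom block.
    """
    idx: list[np.ndarray] = []
    for i in event_indices:
        ev = train.events[i]
        lo = max(0.0, ev.onset_s - pad_s)
        hi = ev.end_s + pad_s
        idx.append(np.arange(int(np.floor(lo * rate_hz)), int(np.ceil(hi * rate_hz))))
    out = np.unique(np.concatenate(idx))
    return out


def regress_roi(
    z: np.ndarray, regressor: Regressor, fit_range: np.ndarray | None = None
) -> float:
    """r² of ordinary least squares of the z trace on the regressor.

    The regression includes an intercept; with a single regressor this
    equals the squared Pearson correlation, so r² is affine-invariant in the
    trace. ``fit_range`` restricts the regression to the given sample
    indices (e.g. the span of the first 10 stimuli).
    """
    z = np.asarray(z, dtype=float)
    x = regressor.samples
    n = min(len(z), len(x))
    z, x = z[:n], x[:n]
    if fit_range is not None:
        fit_range = fit_range[fit_range < n]
        z, x = z[fit_range], x[fit_range]
    if x.std() == 0:
        raise ValueError("zero-variance regressor on the fit range")
    if z.std() == 0:
        return 0.0
    r = np.corrcoef(z, x)[0, 1]
    return float(r * r)


def event_design(
    train: StimulusTrain,
    event_indices: list[int],
    kernel_tau_s: float,
    rate_hz: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Design matrix with one kernel-convolved indicator column per event.

    Giving each presentation its own regressor lets the regression absorb
    arbitrary per-presentation amplitudes, so habituating responses are fit
    as well as stationary ones.
    """
    from .stimulus import _exp_kernel

    if n_samples is None:
        n_samples = int(np.ceil(train.total_duration_s * rate_hz))
    t = np.arange(n_samples) / rate_hz
    kernel = _exp_kernel(kernel_tau_s, rate_hz)
    cols = []
    for i in event_indices:
        ev = train.events[i]
        ind = np.zeros(n_samples)
        ind[(t >= ev.onset_s) & (t < ev.onset_s + ev.expand_s)] = 1.0
        cols.append(np.convolve(ind, kernel)[:n_samples])
    return np.column_stack(cols)


def regress_design(
    traces: np.ndarray, design: np.ndarray, fit_range: np.ndarray | None = None
) -> np.ndarray:
    """r² of OLS (with intercept) of each trace row on a multi-column design."""
    Y = np.atleast_2d(np.asarray(traces, dtype=float))
    X = np.asarray(design, dtype=float)
    if fit_range is not None:
        Y = Y[:, fit_range]
        X = X[fit_range]
    Xi = np.column_stack([np.ones(len(X)), X])
    H = Xi @ np.linalg.pinv(Xi)
    resid = Y - Y @ H.T
    ss_res = np.sum(resid**2, axis=1)
    ss_tot = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)


def select_responsive(r2: pd.Series | np.ndarray) -> ResponsivenessResult:
    """Flag ROIs whose r² exceeds the pooled median + 2 SD (strict).

    The threshold is computed over all supplied ROIs pooled across fish,
    with the sample SD (n-1). With identical r² everywhere the SD is zero
    and no ROI passes the strict inequality.
    """
    if not isinstance(r2, pd.Series):
        r2 = pd.Series(np.asarray(r2, dtype=float))
    if len(r2) < 2:
        raise ValueError("need at least 2 ROIs to form a threshold")
    threshold = float(r2.median() + 2.0 * r2.std(ddof=1))
    return ResponsivenessResult(
        r2=r2.astype(float), threshold=threshold, responsive=r2 > threshold
    )


def noise_sd_estimate(z: np.ndarray) -> float:
    """Robust per-sample noise SD from the median absolute first difference.

    Transients are slow relative to the sampling interval, so successive
    differences are dominated by noise: sd ~ MAD(diff) / (0.6745 * sqrt(2)).
    """
    z = np.asarray(z, dtype=float)
    d = np.diff(z)
    return float(np.median(np.abs(d - np.median(d))) / (0.67448975 * np.sqrt(2.0)))


def expected_noise_max(n_window: int, noise_sd: float) -> float:
    """Expected maximum of ``n_window`` i.i.d. N(0, sd) samples.

    Blom's approximation E[max] ~ sd * Phi^{-1}((n - 0.375)/(n + 0.25)).
    Used to debias window-max response evidence: the max over a stimulus
    window exceeds zero by this much even for a silent ROI.
    """
    from scipy.stats import norm

    if n_window < 1:
        return 0.0
    return float(noise_sd * norm.ppf((n_window - 0.375) / (n_window + 0.25)))


def max_response(
    z: np.ndarray,
    event: StimulusEvent,
    rate_hz: float,
    baseline_s: float = 5.0,
) -> float:
    """Baseline-subtracted maximum response to one stimulus.

    Max of z over [onset, onset + expand + fade) minus the mean of z over
    [onset - baseline_s, onset). A baseline reaching before the record start
    is truncated with a warning.
    """
    if baseline_s <= 0:
        raise ValueError("baseline_s must be > 0")
    z = np.asarray(z, dtype=float)
    i_on = int(round(event.onset_s * rate_hz))
    i_end = int(round(event.end_s * rate_hz))
    i_base = int(round((event.onset_s - baseline_s) * rate_hz))
    if i_base < 0:
        warnings.warn("baseline window truncated at record start", stacklevel=2)
        i_base = 0
    if i_on >= len(z):
        raise ValueError("stimulus window lies beyond the record")
    window = z[i_on : min(i_end, len(z))]
    baseline = z[i_base:i_on]
    base_mean = float(baseline.mean()) if len(baseline) else 0.0
    return float(window.max() - base_mean)


def max_response_matrix(
    z_traces: pd.DataFrame,
    train: StimulusTrain,
    rate_hz: float,
    baseline_s: float = 5.0,
    event_indices: list[int] | None = None,
) -> pd.DataFrame:
    """Max responses for every ROI x stimulus; columns are 1-based stimulus indices."""
    events = list(enumerate(train.events))
    if event_indices is not None:
        events = [(i, train.events[i]) for i in event_indices]
    mat = z_traces.to_numpy(dtype=float)
    cols = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ev in events:
            cols[i + 1] = [
                max_response(row, ev, rate_hz, baseline_s=baseline_s) for row in mat
            ]
    return pd.DataFrame(cols, index=z_traces.index)


def group_mean_responses(
    responses: pd.DataFrame, fish_ids: pd.Series
) -> pd.Series:
    """Two-stage mean over a ROI x stimulus response matrix.

    ROIs are first averaged within fish, then fish means are averaged, so
    every fish carries equal weight regardless of its ROI count. Fish with
    no ROIs in ``responses`` simply do not contribute.
    """
    if len(responses) == 0:
        raise ValueError("no responsive ROIs to average")
    fish = fish_ids.reindex(responses.index)
    if fish.isna().any():
        raise ValueError("every ROI needs a fish id")
    per_fish = responses.groupby(fish).mean()
    return per_fish.mean(axis=0)
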