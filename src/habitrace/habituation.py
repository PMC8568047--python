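"""Component-sensitivity classes and per-ROI habituation-rate fitting.

The component protocol flanks a block of 10 looms with dim/checkerboard
presentations (dim, checker, dim, checker before and after). Responsive
ROIs are classified by their mean baseline-subtracted max response to the
four dims and four checkerboards (threshold in z units), then each ROI's
habituation over the loom block is summarized by fitting

    f(x) = a + b * exp(-c * x),   x = 1..10 (loom index)

to its ten loom max responses. The fit minimizes the sum of absolute
residuals (least absolute residuals, LAR) via iteratively reweighted least
squares, which caps the influence of single-trial outliers. Fits are kept
only when adjusted r² > 0.5 and SSE < 20. Habituation rates (c) are
compared across sensitivity classes with a Friedman test over per-fish
class medians.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .responsiveness import (
    event_design,
    expected_noise_max,
    fit_range_for_events,
    max_response_matrix,
    noise_sd_estimate,
    regress_design,
    select_responsive,
    zscore_pooled,
)
from .stimulus import StimulusKind, StimulusTrain

__all__ = [
    "ComponentClass",
    "DecayFit",
    "FriedmanResult",
    "GroupDecayStats",
    "PipelineError",
    "classify_components",
    "fit_decay",
    "fit_decay_ols",
    "friedman_test",
    "run_experiment3",
]

DEFAULT_CLASS_THRESHOLD_Z = 1.0
ADJ_R2_MIN = 0.5
SSE_MAX = 20.0
C_BOUNDS = (0.0, 10.0)
_C_STARTS = (0.05, 0.3, 0.7, 1.5)
_IRLS_DELTA = 1e-6
_IRLS_MAX_ITER = 200
_IRLS_TOL = 1e-9
# IRLS for an L1 objective converges only linearly; once the objective stops
# improving by this relative amount per sweep the fit is treated as converged
_IRLS_OBJ_TOL = 1e-5


def _sst(y: np.ndarray) -> float:
    """Total sum of squares, snapped to zero for constant sequences."""
    if np.ptp(y) == 0:
        return 0.0
    return float(np.sum((y - y.mean()) ** 2))


@dataclass(frozen=True)
class ComponentClass:
    """Sensitivity class of one ROI with the evidence behind it."""

    roi_id: int
    label: str  # dim / checker / both / none
    dim_evidence: float  # mean max response to the flanking dims, z units
    checker_evidence: float  # mean max response to the flanking checkerboards


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit f(x) = a + b exp(-c x) with diagnostics."""

    a: float
    b: float
    c: float
    adj_r2: float
    sse: float
    accepted: bool
    converged: bool = True


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_blocks: int
    method: str  # "exact" or "chi2"


@dataclass
class GroupDecayStats:
    """Per-fish class medians of c and the Friedman comparison across classes."""

    medians: pd.DataFrame  # fish x class
    friedman: FriedmanResult
    dropped_fish: list = field(default_factory=list)


class PipelineError(RuntimeError):
    """A pipeline stage produced no usable ROIs."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def classify_components(
    dim_responses: np.ndarray,
    checker_responses: np.ndarray,
    threshold: float = DEFAULT_CLASS_THRESHOLD_Z,
    roi_id: int = -1,
) -> ComponentClass:
    """Classify one ROI from its flanking dim and checkerboard responses.

    Dim-sensitive iff the mean dim max response exceeds ``threshold``;
    checkerboard-sensitive iff the mean checkerboard response does; 'both'
    when both do, 'none' when neither.
    """
    dim_responses = np.asarray(dim_responses, dtype=float)
    checker_responses = np.asarray(checker_responses, dtype=float)
    if len(dim_responses) == 0 or len(checker_responses) == 0:
        raise ValueError("missing stimulus responses")
    if np.any(~np.isfinite(dim_responses)) or np.any(~np.isfinite(checker_responses)):
        raise ValueError("non-finite stimulus responses")
    d = float(dim_responses.mean())
    c = float(checker_responses.mean())
    if d > threshold and c > threshold:
        label = "both"
    elif d > threshold:
        label = "dim"
    elif c > threshold:
        label = "checker"
    else:
        label = "none"
    return ComponentClass(roi_id=roi_id, label=label, dim_evidence=d, checker_evidence=c)


def _profiled_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, c: float) -> tuple[float, float, float]:
    """For fixed c, closed-form weighted LS for (a, b); returns (a, b, wss)."""
    e = np.exp(-c * x)
    sw = float(w.sum())
    se = float(w @ e)
    see = float(w @ (e * e))
    sy = float(w @ y)
    sey = float(w @ (e * y))
    det = sw * see - se * se
    if det <= 1e-14 * max(sw * see, 1e-300):
        # exp column numerically collinear with the intercept (c very large)
        a = sy / sw
        resid = y - a
        return a, 0.0, float(w @ (resid * resid))
    b = (sw * sey - se * sy) / det
    a = (sy - b * se) / sw
    resid = y - (a + b * e)
    return float(a), float(b), float(w @ (resid * resid))


def _wls_fit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, xatol: float = 1e-10
) -> tuple[float, float, float]:
    """Weighted LS of a + b exp(-c x); (a, b) profiled out, c by bounded search."""

    def obj(c: float) -> float:
        return _profiled_wls(x, y, w, c)[2]

    res = optimize.minimize_scalar(
        obj, bounds=C_BOUNDS, method="bounded", options={"xatol": xatol}
    )
    c = float(res.x)
    a, b, _ = _profiled_wls(x, y, w, c)
    return a, b, c


def fit_decay(
    responses: np.ndarray,
    x: np.ndarray | None = None,
    *,
    adj_r2_min: float = ADJ_R2_MIN,
    sse_max: float = SSE_MAX,
) -> DecayFit:
    """Robust LAR fit of f(x) = a + b exp(-c x) to per-presentation responses.

    Minimizes the sum of absolute residuals by IRLS: repeated weighted least
    squares with weights 1/max(|residual|, 1e-6), up to 200 iterations,
    parameter tolerance 1e-9, multi-started over c in {0.05, 0.3, 0.7, 1.5}
    with c bounded to [0, 10]. ``x`` defaults to the 1-based presentation
    index. Adjusted r² uses p = 3 parameters; SSE is the plain sum of
    squared residuals of the accepted curve. The fit is accepted when
    adjusted r² > ``adj_r2_min`` and SSE < ``sse_max``.
    """
    y = np.asarray(responses, dtype=float)
    if x is None:
        x = np.arange(1, len(y) + 1, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("responses and x must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    n = len(y)

    best: tuple[float, float, float, float, bool] | None = None  # l1, a, b, c, conv
    for c0 in _C_STARTS:
        # start-specific initial weights from the profiled fit at c = c0
        a, b, _ = _profiled_wls(x, y, np.ones(n), c0)
        c = c0
        converged = False
        l1_prev = np.inf
        for _ in range(_IRLS_MAX_ITER):
            resid = y - (a + b * np.exp(-c * x))
            w = 1.0 / np.maximum(np.abs(resid), _IRLS_DELTA)
            a_new, b_new, c_new = _wls_fit(x, y, w)
            l1_new = float(np.sum(np.abs(y - (a_new + b_new * np.exp(-c_new * x)))))
            param_delta = max(abs(a_new - a), abs(b_new - b), abs(c_new - c))
            a, b, c = a_new, b_new, c_new
            # oscillation between equivalent weightings counts as converged
            if param_delta < _IRLS_TOL or abs(l1_new - l1_prev) < _IRLS_OBJ_TOL * (1.0 + l1_new):
                converged = True
                break
            l1_prev = l1_new
        l1 = float(np.sum(np.abs(y - (a + b * np.exp(-c * x)))))
        if best is None or l1 < best[0] - 1e-12:
            best = (l1, a, b, c, converged)

    assert best is not None
    _, a, b, c, converged = best
    fitted = a + b * np.exp(-c * x)
    sse = float(np.sum((y - fitted) ** 2))
    sst = _sst(y)
    p_params = 3
    if sst == 0 or n <= p_params:
        adj_r2 = -np.inf
    else:
        adj_r2 = 1.0 - (sse / (n - p_params)) / (sst / (n - 1))
    accepted = bool(converged and adj_r2 > adj_r2_min and sse < sse_max)
    return DecayFit(
        a=float(a), b=float(b), c=float(c), adj_r2=float(adj_r2), sse=sse,
        accepted=accepted, converged=converged,
    )


def _batch_profiled_wss(
    Y: np.ndarray, W: np.ndarray, c: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise closed-form weighted LS of a + b exp(-c_i x); returns (a, b, wss)."""
    E = np.exp(-np.outer(c, x))  # N x m
    sw = W.sum(axis=1)
    se = np.einsum("ij,ij->i", W, E)
    see = np.einsum("ij,ij->i", W, E * E)
    sy = np.einsum("ij,ij->i", W, Y)
    sey = np.einsum("ij,ij->i", W, E * Y)
    det = sw * see - se * se
    ok = det > 1e-14 * np.maximum(sw * see, 1e-300)
    b = np.where(ok, (sw * sey - se * sy) / np.where(ok, det, 1.0), 0.0)
    a = np.where(ok, (sy - b * se) / sw, sy / sw)
    R = Y - (a[:, None] + b[:, None] * E)
    wss = np.einsum("ij,ij->i", W, R * R)
    return a, b, wss


def _batch_wls_fit(
    Y: np.ndarray, W: np.ndarray, x: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise weighted fit with c found by golden-section search on [0, 10]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    n = len(Y)
    lo = np.full(n, C_BOUNDS[0])
    hi = np.full(n, C_BOUNDS[1])
    c1 = hi - invphi * (hi - lo)
    c2 = lo + invphi * (hi - lo)
    f1 = _batch_profiled_wss(Y, W, c1, x)[2]
    f2 = _batch_profiled_wss(Y, W, c2, x)[2]
    n_iter = int(np.ceil(np.log(tol / (C_BOUNDS[1] - C_BOUNDS[0])) / np.log(invphi)))
    for _ in range(n_iter):
        left = f1 < f2  # minimum lies in [lo, c2]
        hi = np.where(left, c2, hi)
        lo = np.where(left, lo, c1)
        c1_new = np.where(left, hi - invphi * (hi - lo), c2)
        c2_new = np.where(left, c1, lo + invphi * (hi - lo))
        probe = np.where(left, c1_new, c2_new)
        f_probe = _batch_profiled_wss(Y, W, probe, x)[2]
        f1_new = np.where(left, f_probe, f2)
        f2_new = np.where(left, f1, f_probe)
        c1, c2, f1, f2 = c1_new, c2_new, f1_new, f2_new
    c = (lo + hi) / 2.0
    a, b, _ = _batch_profiled_wss(Y, np.asarray(W), c, x)
    return a, b, c


def fit_decay_batch(
    responses: np.ndarray,
    x: np.ndarray | None = None,
    *,
    robust: bool = True,
    adj_r2_min: float = ADJ_R2_MIN,
    sse_max: float = SSE_MAX,
) -> pd.DataFrame:
    """Vectorized decay fitting for many ROIs sharing the same x grid.

    Same model, IRLS scheme and acceptance rule as :func:`fit_decay`, run
    row-wise over a (n_rois, n_presentations) response matrix.
    ``robust=False`` gives the plain least-squares comparison fit. Returns a
    DataFrame with columns a, b, c, adj_r2, sse, accepted.
    """
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    n, m = Y.shape
    if x is None:
        x = np.arange(1, m + 1, dtype=float)
    else:
        x = np.asarray(x, dtype=float)

    if not robust:
        a, b, c = _batch_wls_fit(Y, np.ones_like(Y), x)
        converged = np.ones(n, dtype=bool)
    else:
        best_l1 = np.full(n, np.inf)
        a = np.zeros(n)
        b = np.zeros(n)
        c = np.zeros(n)
        converged = np.zeros(n, dtype=bool)
        for c0 in _C_STARTS:
            c_cur = np.full(n, c0)
            a_cur, b_cur, _ = _batch_profiled_wss(Y, np.ones_like(Y), c_cur, x)
            conv = np.zeros(n, dtype=bool)
            l1_prev = np.full(n, np.inf)
            for _ in range(_IRLS_MAX_ITER):
                R = Y - (a_cur[:, None] + b_cur[:, None] * np.exp(-np.outer(c_cur, x)))
                W = 1.0 / np.maximum(np.abs(R), _IRLS_DELTA)
                a_new, b_new, c_new = _batch_wls_fit(Y, W, x)
                delta = np.maximum.reduce(
                    [np.abs(a_new - a_cur), np.abs(b_new - b_cur), np.abs(c_new - c_cur)]
                )
                a_cur, b_cur, c_cur = a_new, b_new, c_new
                l1_new = np.sum(
                    np.abs(Y - (a_cur[:, None] + b_cur[:, None] * np.exp(-np.outer(c_cur, x)))),
                    axis=1,
                )
                conv |= (delta < _IRLS_TOL) | (
                    np.abs(l1_new - l1_prev) < _IRLS_OBJ_TOL * (1.0 + l1_new)
                )
                l1_prev = l1_new
                if conv.all():
                    break
            l1 = np.sum(
                np.abs(Y - (a_cur[:, None] + b_cur[:, None] * np.exp(-np.outer(c_cur, x)))),
                axis=1,
            )
            better = l1 < best_l1 - 1e-12
            best_l1 = np.where(better, l1, best_l1)
            a = np.where(better, a_cur, a)
            b = np.where(better, b_cur, b)
            c = np.where(better, c_cur, c)
            converged = np.where(better, conv, converged)

    fitted = a[:, None] + b[:, None] * np.exp(-np.outer(c, x))
    sse = np.sum((Y - fitted) ** 2, axis=1)
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    sst[np.ptp(Y, axis=1) == 0] = 0.0
    p_params = 3
    with np.errstate(invalid="ignore", divide="ignore"):
        adj_r2 = np.where(
            (sst > 0) & (m > p_params),
            1.0 - (sse / (m - p_params)) / np.where(sst > 0, sst / (m - 1), 1.0),
            -np.inf,
        )
    accepted = converged & (adj_r2 > adj_r2_min) & (sse < sse_max)
    return pd.DataFrame(
        {"a": a, "b": b, "c": c, "adj_r2": adj_r2, "sse": sse, "accepted": accepted}
    )


def fit_decay_ols(responses: np.ndarray, x: np.ndarray | None = None) -> DecayFit:
    """Plain (non-robust) least-squares fit of the same decay model.

    Kept as the comparison estimator for outlier-robustness checks.
    """
    y = np.asarray(responses, dtype=float)
    if x is None:
        x = np.arange(1, len(y) + 1, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    n = len(y)
    a, b, c = _wls_fit(x, y, np.ones(n))
    sse = float(np.sum((y - (a + b * np.exp(-c * x))) ** 2))
    sst = _sst(y)
    adj_r2 = 1.0 - (sse / (n - 3)) / (sst / (n - 1)) if sst > 0 and n > 3 else -np.inf
    accepted = bool(adj_r2 > ADJ_R2_MIN and sse < SSE_MAX)
    return DecayFit(a=a, b=b, c=c, adj_r2=float(adj_r2), sse=sse, accepted=accepted)


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-block mid-ranks."""
    b, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((col_sums - b * (k + 1) / 2.0) ** 2))
    den = float(np.sum((ranks - (k + 1) / 2.0) ** 2))
    if den == 0:
        return 0.0
    return num / den


def friedman_test(blocks: np.ndarray, exact_max_blocks: int = 8) -> FriedmanResult:
    """Friedman test over a complete block design (rows = fish, cols = classes).

    Within-block mid-ranks with tie correction. For up to
    ``exact_max_blocks`` blocks the p-value is computed by full enumeration
    of all within-block column permutations ((k!)^b); beyond that the
    chi-square approximation with k-1 degrees of freedom is used.
    """
    data = np.asarray(blocks, dtype=float)
    if data.ndim != 2:
        raise ValueError("blocks must be a 2-D fish x class matrix")
    b, k = data.shape
    if b < 2:
        raise ValueError("need at least 2 blocks (fish)")
    if np.any(~np.isfinite(data)):
        raise ValueError("incomplete blocks: drop fish missing a class first")
    ranks = np.vstack([stats.rankdata(row) for row in data])
    observed = _friedman_statistic(ranks)
    if np.ptp(data, axis=1).max() == 0:
        return FriedmanResult(statistic=0.0, p_value=1.0, n_blocks=b, method="exact")

    if b <= exact_max_blocks:
        perms = np.array(list(itertools.permutations(range(k))))  # k! x k
        n_perm = len(perms)
        # per block: all k! permuted rank rows
        block_perms = [ranks[i][perms] for i in range(b)]  # each k! x k
        col_sums = np.zeros((1, k))
        for bp in block_perms:
            col_sums = (col_sums[:, None, :] + bp[None, :, :]).reshape(-1, k)
        num = (k - 1) * np.sum((col_sums - b * (k + 1) / 2.0) ** 2, axis=1)
        den = float(np.sum((ranks - (k + 1) / 2.0) ** 2))
        all_stats = num / den
        p = float(np.mean(all_stats >= observed - 1e-12))
        return FriedmanResult(statistic=observed, p_value=p, n_blocks=b, method="exact")
    p = float(stats.chi2.sf(observed, k - 1))
    return FriedmanResult(statistic=observed, p_value=p, n_blocks=b, method="chi2")


def run_experiment3(
    cohort,
    *,
    threshold: float = DEFAULT_CLASS_THRESHOLD_Z,
    baseline_s: float = 5.0,
    rate_hz: float | None = None,
) -> tuple[GroupDecayStats, pd.DataFrame]:
    """Full component-sensitivity habituation analysis on one cohort.

    Chain: z-score -> responsiveness regression on the eight flanking
    component stimuli (median + 2 SD r² threshold) -> component
    classification -> LAR decay fit on the 10-loom block -> goodness-of-fit
    filter -> per-fish class medians of c -> Friedman test.

    Returns the group statistics and a per-ROI table (r², responsive, label,
    evidence, fit parameters, accepted).
    """
    train: StimulusTrain = cohort.train
    rate = rate_hz if rate_hz is not None else cohort.config.rate_hz
    kinds = [ev.kind for ev in train.events]
    dim_idx = [i for i, kk in enumerate(kinds) if kk is StimulusKind.DIM]
    chk_idx = [i for i, kk in enumerate(kinds) if kk is StimulusKind.CHECKERBOARD]
    loom_idx = [i for i, kk in enumerate(kinds) if kk is StimulusKind.LOOM]
    component_idx = sorted(dim_idx + chk_idx)
    if not component_idx or not loom_idx:
        raise PipelineError("train", "protocol lacks component or loom stimuli")

    z = zscore_pooled(cohort.traces)
    if len(z) == 0:
        raise PipelineError("zscore", "no non-constant traces")

    # one regressor per flanking component stimulus: the regression absorbs
    # per-presentation (habituating) amplitudes
    design = event_design(
        train, component_idx, cohort.config.kernel_tau_s, rate,
        n_samples=z.shape[1],
    )
    fr = fit_range_for_events(train, component_idx, rate)
    zmat = z.to_numpy(dtype=float)
    r2 = pd.Series(regress_design(zmat, design, fr), index=z.index, name="r2")
    sel = select_responsive(r2)
    responsive_ids = sel.responsive[sel.responsive].index
    if len(responsive_ids) == 0:
        raise PipelineError("responsiveness", "no ROIs passed the r² threshold")

    z_resp = z.loc[responsive_ids]
    dim_m = max_response_matrix(z_resp, train, rate, baseline_s, event_indices=dim_idx)
    chk_m = max_response_matrix(z_resp, train, rate, baseline_s, event_indices=chk_idx)
    loom_m = max_response_matrix(z_resp, train, rate, baseline_s, event_indices=loom_idx)

    # Window maxima over noise alone sit well above zero (extreme-value
    # bias); subtract each ROI's expected noise-window maximum so the class
    # threshold acts on genuine stimulus-evoked excess.
    ev0 = train.events[dim_idx[0]]
    n_window = int(round((ev0.expand_s + ev0.fade_s) * rate))
    z_resp_mat = z_resp.to_numpy(dtype=float)
    noise_bias = np.array(
        [expected_noise_max(n_window, noise_sd_estimate(row)) for row in z_resp_mat]
    )
    bias = pd.Series(noise_bias, index=z_resp.index)

    fish_of = {r.roi_id: r.fish_id for r in cohort.rois}
    rows = []
    for rid in responsive_ids:
        cc = classify_components(
            dim_m.loc[rid].to_numpy() - bias.loc[rid],
            chk_m.loc[rid].to_numpy() - bias.loc[rid],
            threshold=threshold, roi_id=rid,
        )
        rows.append(
            {
                "roi_id": rid,
                "fish_id": fish_of.get(rid),
                "r2": r2.loc[rid],
                "label": cc.label,
                "dim_evidence": cc.dim_evidence,
                "checker_evidence": cc.checker_evidence,
            }
        )
    table = pd.DataFrame(rows).set_index("roi_id")
    classified = table[table["label"] != "none"]
    if len(classified) == 0:
        raise PipelineError("classification", "no ROI exceeded the class threshold")

    fit_df = fit_decay_batch(loom_m.loc[classified.index].to_numpy())
    fit_df.index = classified.index
    table = table.join(fit_df)
    accepted = table[table["accepted"] == True]  # noqa: E712
    if len(accepted) == 0:
        raise PipelineError("decay_fit", "no accepted decay fits")

    med = (
        accepted.groupby(["fish_id", "label"], observed=True)["c"]
        .median()
        .unstack("label")
        .reindex(columns=["dim", "checker", "both"])
    )
    complete = med.dropna()
    dropped = sorted(set(med.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"dropping fish without all three classes: {dropped}", stacklevel=2
        )
    if len(complete) < 2:
        raise PipelineError("friedman", "fewer than 2 fish with complete class blocks")
    fr_res = friedman_test(complete.to_numpy())
    stats_out = GroupDecayStats(medians=complete, friedman=fr_res, dropped_fish=dropped)
    return stats_out, table
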