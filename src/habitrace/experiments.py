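"""End-to-end validation experiments on synthetic cohorts.

Each function generates seeded synthetic data with known ground truth, runs
the corresponding slice of the analysis pipeline, and returns summary
numbers (recovery errors, test calibration, classification quality, power).
They are the package's self-checks and the basis of the acceptance script.

Problem sizes are chosen to estimate each quantity stably on a single CPU
in a few minutes: 500-1000 ROIs for fit recovery, 1000 replicates for test
calibration, 50 seeds for the headline non-rejection rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .behavior import escape_matrix, escape_probability, fit_escape_decay, filter_fish
from .behavior import test_habituation as habituation_ats
from .clustering import validate_clusters
from .habituation import fit_decay_batch, friedman_test, run_experiment3
from .responsiveness import max_response_matrix, zscore_pooled
from .stimulus import StimulusKind, build_train
from .synthetic import (
    CohortConfig,
    ConstantEscapeModel,
    LoomEscapeModel,
    generate_behavior,
    generate_cohort,
)

__all__ = [
    "decay_recovery",
    "decay_robustness",
    "rank_test_calibration",
    "oracle_equivalence",
    "pipeline_recovery",
    "headline_reproduction",
    "cluster_rule_boundaries",
    "behavior_recovery",
]


def _loom_max_responses(cohort, rate_hz: float = 2.0):
    """z-score traces and extract per-ROI max responses to the loom block."""
    train = cohort.train
    loom_idx = [
        i for i, ev in enumerate(train.events) if ev.kind is StimulusKind.LOOM
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = zscore_pooled(cohort.traces)
        lm = max_response_matrix(z, train, rate_hz, 5.0, event_indices=loom_idx)
    return lm


def decay_recovery(
    seed: int, n_rois: int = 500, amplitude: float = 3.0, noise_sd: float = 0.5
) -> dict:
    """Habituation-rate recovery from simulated traces.

    ROIs with c ~ U(0.2, 1.2) respond to the 10-loom block; their traces are
    z-scored, loom max responses extracted and fit with the robust decay
    model. Reports the median relative error of accepted ĉ.
    """
    n_fish = 2
    cfg = CohortConfig(
        n_fish=n_fish,
        rois_per_fish=n_rois // n_fish,
        class_mixture={"checker": 1.0},
        amplitude=amplitude,
        noise_sd=noise_sd,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_cohort(cfg, seed=seed)
    lm = _loom_max_responses(cohort)
    fits = fit_decay_batch(lm.to_numpy())
    fits.index = lm.index
    truth = cohort.roi_table["decay_c"].reindex(lm.index)
    acc = fits["accepted"]
    rel_err = (fits["c"] - truth).abs() / truth
    return {
        "n_fits": int(len(fits)),
        "n_accepted": int(acc.sum()),
        "median_rel_err_c": float(rel_err[acc].median()),
    }


def decay_robustness(seed: int, n_rois: int = 1000, outlier_z: float = 5.0) -> dict:
    """LAR vs plain least squares under single-presentation outliers.

    Each ROI's loom max-response sequence gets +``outlier_z`` z added at one
    random loom (10% of its points). Reports median relative ĉ errors for
    both estimators over all ROIs.
    """
    n_fish = 4
    cfg = CohortConfig(
        n_fish=n_fish,
        rois_per_fish=n_rois // n_fish,
        class_mixture={"checker": 1.0},
        amplitude=3.0,
        noise_sd=0.5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_cohort(cfg, seed=seed)
    lm = _loom_max_responses(cohort).to_numpy()
    rng = np.random.default_rng(seed + 1)
    lm[np.arange(len(lm)), rng.integers(0, lm.shape[1], len(lm))] += outlier_z
    truth = cohort.roi_table["decay_c"].to_numpy()
    lar = fit_decay_batch(lm)
    ols = fit_decay_batch(lm, robust=False)
    lar_err = np.abs(lar["c"].to_numpy() - truth) / truth
    ols_err = np.abs(ols["c"].to_numpy() - truth) / truth
    return {
        "n_rois": int(len(lm)),
        "lar_median_rel_err": float(np.median(lar_err)),
        "ols_median_rel_err": float(np.median(ols_err)),
    }


def rank_test_calibration(
    seed: int, n_reps: int = 1000, alpha: float = 0.05
) -> dict:
    """Type-I error of the ATS habituation test and the Friedman test.

    Exchangeable nulls: i.i.d. normal responses across three time points for
    20 fish (ATS); i.i.d. normal class medians across three classes for 11
    fish (Friedman).
    """
    rng = np.random.default_rng(seed)
    ats_rej = 0
    for _ in range(n_reps):
        d = rng.normal(size=(20, 3))
        if habituation_ats(d[:, 0], d[:, 1], d[:, 2]).p_value < alpha:
            ats_rej += 1
    fr_rej = 0
    for _ in range(n_reps):
        d = rng.normal(size=(11, 3))
        if friedman_test(d).p_value < alpha:
            fr_rej += 1
    return {
        "n_reps": n_reps,
        "ats_type1": ats_rej / n_reps,
        "friedman_type1": fr_rej / n_reps,
    }


def oracle_equivalence(seed: int) -> dict:
    """Agreement of the fast statistics with brute-force oracles.

    Friedman vs full (k!)^b enumeration on 4-block designs; Mann-Whitney vs
    full combination enumeration at combined n <= 10; regression r² vs the
    squared-Pearson closed form.
    """
    import itertools

    from scipy import stats as sstats

    from .behavior import mann_whitney_u
    from .responsiveness import regress_roi
    from .stimulus import build_regressor

    rng = np.random.default_rng(seed)

    # Friedman vs enumeration
    fr_stat_diff = fr_p_diff = 0.0
    for _ in range(5):
        data = rng.normal(size=(4, 3))
        res = friedman_test(data)
        ranks = np.vstack([sstats.rankdata(row) for row in data])
        b, k = ranks.shape

        def stat(R):
            col = R.sum(axis=0)
            num = (k - 1) * np.sum((col - b * (k + 1) / 2) ** 2)
            return num / np.sum((R - (k + 1) / 2) ** 2)

        obs = stat(ranks)
        hits = total = 0
        for perms in itertools.product(
            itertools.permutations(range(k)), repeat=b
        ):
            R = np.vstack([ranks[i, list(p)] for i, p in enumerate(perms)])
            total += 1
            hits += stat(R) >= obs - 1e-12
        fr_stat_diff = max(fr_stat_diff, abs(res.statistic - obs))
        fr_p_diff = max(fr_p_diff, abs(res.p_value - hits / total))

    # Mann-Whitney vs enumeration
    mwu_p_diff = 0.0
    for _ in range(5):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        _, p_raw, _ = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sstats.rankdata(pooled)
        nx = len(x)
        u_all = np.array(
            [
                sum(ranks[i] for i in ix) - nx * (nx + 1) / 2
                for ix in itertools.combinations(range(len(pooled)), nx)
            ]
        )
        obs = sum(ranks[:nx]) - nx * (nx + 1) / 2
        p_lo = np.mean(u_all <= obs + 1e-12)
        p_hi = np.mean(u_all >= obs - 1e-12)
        p_exact = min(1.0, 2.0 * min(p_lo, p_hi))
        mwu_p_diff = max(mwu_p_diff, abs(p_raw - p_exact))

    # r² vs squared correlation
    train = build_train("imaging1_loom", seed=0)
    reg = build_regressor(train, {"loom"})
    r2_diff = 0.0
    for _ in range(5):
        trace = reg.samples + rng.normal(0, 1.0, size=len(reg))
        r2 = regress_roi(trace, reg)
        r = np.corrcoef(trace, reg.samples)[0, 1]
        r2_diff = max(r2_diff, abs(r2 - r * r))

    return {
        "friedman_stat_max_diff": float(fr_stat_diff),
        "friedman_p_max_diff": float(fr_p_diff),
        "mwu_p_max_diff": float(mwu_p_diff),
        "r2_max_diff": float(r2_diff),
    }


def pipeline_recovery(seed: int, n_fish: int = 11, rois_per_fish: int = 500) -> dict:
    """Ground-truth recovery of the full component-sensitivity pipeline.

    Default cohort (amplitude 3, noise 1): responsiveness sensitivity and
    specificity against true class labels, and the accuracy of the
    dim/checker/both classification among selected truly-responsive ROIs.
    """
    cfg = CohortConfig(n_fish=n_fish, rois_per_fish=rois_per_fish)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_cohort(cfg, seed=seed)
        stats_out, table = run_experiment3(cohort)
    truth = cohort.roi_table["label"]
    truly_responsive = truth != "none"
    selected = pd.Series(truth.index.isin(table.index), index=truth.index)
    sens = float((selected & truly_responsive).sum() / truly_responsive.sum())
    spec = float(((~selected) & (~truly_responsive)).sum() / (~truly_responsive).sum())
    hit_ids = truth.index[selected & truly_responsive]
    acc = float((truth.loc[hit_ids] == table["label"].reindex(hit_ids)).mean())
    return {
        "n_rois": int(len(truth)),
        "n_selected": int(selected.sum()),
        "sensitivity": sens,
        "specificity": spec,
        "class_accuracy": acc,
        "friedman_p": float(stats_out.friedman.p_value),
    }


def headline_reproduction(
    seed: int,
    n_null_seeds: int = 50,
    n_alt_seeds: int = 20,
    n_fish: int = 11,
    rois_per_fish: int = 300,
) -> dict:
    """The class-independent habituation result, in silico.

    Null cohorts share one decay constant across sensitivity classes: the
    Friedman comparison should not reject. Alternative cohorts give
    dim-sensitive ROIs a slower rate (0.2 vs 0.8): it should.
    """
    rng = np.random.default_rng(seed)

    def run(class_c):
        cfg = CohortConfig(
            n_fish=n_fish,
            rois_per_fish=rois_per_fish,
            class_decay_c=class_c,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = generate_cohort(cfg, seed=int(rng.integers(2**31)))
            stats_out, _ = run_experiment3(cohort)
        return stats_out.friedman.p_value

    equal_c = {"dim": 0.6, "checker": 0.6, "both": 0.6}
    null_ps = [run(equal_c) for _ in range(n_null_seeds)]
    alt_c = {"dim": 0.2, "checker": 0.8, "both": 0.8}
    alt_ps = [run(alt_c) for _ in range(n_alt_seeds)]
    return {
        "n_null_seeds": n_null_seeds,
        "null_nonreject_rate": float(np.mean(np.array(null_ps) > 0.05)),
        "n_alt_seeds": n_alt_seeds,
        "alt_power": float(np.mean(np.array(alt_ps) < 0.05)),
    }


def cluster_rule_boundaries(seed: int) -> dict:
    """Exercise each cluster-validation criterion at its boundary.

    Builds single-cluster fixtures straddling the four cutoffs (99 vs 100
    members; 8/11 vs 9/11 fish; 33% vs 34% single-fish share; member
    correlation at 0.5) and counts correct retain/reject decisions.
    """
    from .clustering import ClusterResult

    rng = np.random.default_rng(seed)
    profile = np.zeros(60)
    profile[20:30] = 4.0

    def fixture(n_members, n_fish_present, share0=None, flip=0):
        good = n_members - flip
        block = np.vstack(
            [profile + rng.normal(0, 0.1, 60) for _ in range(good)]
            + [-profile + rng.normal(0, 0.1, 60) for _ in range(flip)]
        )
        z = pd.DataFrame(block)
        if share0 is not None:
            n0 = int(round(share0 * n_members))
            others = np.arange(n_members - n0) % (n_fish_present - 1) + 1
            fish = pd.Series(np.r_[np.zeros(n0, int), others], index=z.index)
        else:
            fish = pd.Series(np.arange(n_members) % n_fish_present, index=z.index)
        assignments = pd.Series(np.zeros(n_members, int), index=z.index)
        means = pd.DataFrame({0: z.mean(axis=0)}).T
        res = ClusterResult(assignments=assignments, means=means, inertia=0.0)
        return validate_clusters(res, z, fish, n_fish=11).validity[0]

    checks = [
        fixture(99, 11).retained is False,  # too small
        fixture(100, 11).retained is True,
        fixture(120, 8).retained is False,  # 72.7% of fish < 75%
        fixture(120, 9).retained is True,  # 81.8%
        fixture(300, 10, share0=0.34).retained is False,  # one fish > 33%
        fixture(300, 10, share0=0.33).retained is True,
        fixture(140, 11, flip=30).n_members == 110,  # incoherent members pruned
        fixture(140, 11, flip=30).retained is True,
    ]
    return {"n_checks": len(checks), "n_passed": int(sum(checks))}


def behavior_recovery(
    seed: int,
    n_reps: int = 25,
    n_fish: int = 24,
    p0: float = 0.8,
    lam: float = 0.25,
    alpha_bonferroni: float = 0.05 / 8,
) -> dict:
    """Behavioral habituation: test power and decay-rate recovery.

    Habituating loom cohorts (p_k = p0 exp(-lam (k-1))) should test
    significant with the three-time-point ATS and yield a one-phase-decay
    rate near lam; flat-probability checkerboard cohorts (the exchangeable
    null) should stay non-significant at the Bonferroni-adjusted level.
    """
    rng = np.random.default_rng(seed)
    sig = 0
    k_errs = []
    for _ in range(n_reps):
        train = build_train("behavior_loom", seed=int(rng.integers(2**31)))
        recs = generate_behavior(
            n_fish, train, LoomEscapeModel(p0=p0, lam=lam), seed=int(rng.integers(2**31))
        )
        recs = filter_fish(recs)
        mat = escape_matrix(recs, train)
        ats = habituation_ats(mat[:, 0], mat[:, 19], mat[:, 20])
        sig += ats.p_value < 0.05
        fit = fit_escape_decay(escape_probability(recs, train))
        k_errs.append(abs(fit.K - lam) / lam)

    nonsig = 0
    for _ in range(n_reps):
        train = build_train("behavior_checker", seed=int(rng.integers(2**31)))
        recs = filter_fish(
            generate_behavior(
                n_fish, train, ConstantEscapeModel(p=0.35), seed=int(rng.integers(2**31))
            )
        )
        mat = escape_matrix(recs, train)
        nonsig += habituation_ats(mat[:, 0], mat[:, 19], mat[:, 20]).p_value >= alpha_bonferroni

    return {
        "n_reps": n_reps,
        "loom_power": sig / n_reps,
        "decay_rate_median_rel_err": float(np.median(k_errs)),
        "checker_nonsignificant_rate": nonsig / n_reps,
    }
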