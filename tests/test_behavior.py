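import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitrace import (
    BehaviorRecord,
    ConstantEscapeModel,
    EscapeCurve,
    classify_movement,
    escape_probability,
    filter_fish,
    fit_escape_decay,
    generate_behavior,
    mann_whitney_u,
)
from habitrace import test_habituation as ats_habituation
from habitrace.behavior import escape_matrix
from habitrace.stimulus import build_train


class TestClassifyMovement:
    @pytest.mark.parametrize(
        "speed, expected",
        [
            (0.3, "drift"),
            (12.0, "scoot"),
            (45.0, "escape"),
            (0.5, "scoot"),  # boundary: closed scoot interval
            (30.0, "scoot"),  # boundary: closed scoot interval
            (0.0, "drift"),
        ],
    )
    def test_speed_classes(self, speed, expected):
        assert classify_movement(speed) == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            classify_movement(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partitions_nonnegative_speeds(self, speed):
        assert classify_movement(speed) in {"drift", "scoot", "escape"}


class TestFilterFish:
    def test_never_escaping_fish_excluded(self):
        slow = BehaviorRecord(fish_id=0, bins_mm=np.full(100, 5.0))
        fast = BehaviorRecord(fish_id=1, bins_mm=np.r_[np.full(99, 5.0), 40.0])
        kept = filter_fish([slow, fast])
        assert [r.fish_id for r in kept] == [1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_fish([])

    def test_all_excluded_gives_empty_list(self):
        slow = BehaviorRecord(fish_id=0, bins_mm=np.full(10, 1.0))
        assert filter_fish([slow]) == []


class TestEscapeProbability:
    def _records_with_escapes(self, train, escaping_fish, stim_index=0):
        ev = train.events[stim_index]
        n_sec = int(np.ceil(train.total_duration_s))
        recs = []
        for fish in range(12):
            bins = np.full(n_sec, 1.0)
            if fish in escaping_fish:
                bins[int(ev.onset_s) + 1] = 50.0
            recs.append(BehaviorRecord(fish_id=fish, bins_mm=bins))
        return recs

    def test_half_the_fish_escaping_gives_half(self):
        train = build_train("behavior_loom", seed=0)
        recs = self._records_with_escapes(train, escaping_fish=set(range(6)))
        curve = escape_probability(recs, train)
        assert curve.p[0] == pytest.approx(0.5)
        assert np.all(curve.p[1:] == 0.0)

    def test_no_escapes_gives_zero_curve(self):
        train = build_train("behavior_loom", seed=0)
        recs = self._records_with_escapes(train, escaping_fish=set())
        curve = escape_probability(recs, train)
        assert np.all(curve.p == 0.0)

    def test_fish_order_invariance(self):
        train = build_train("behavior_loom", seed=0)
        recs = self._records_with_escapes(train, escaping_fish={0, 3, 7})
        curve1 = escape_probability(recs, train)
        curve2 = escape_probability(recs[::-1], train)
        assert np.array_equal(curve1.p, curve2.p)

    def test_bins_outside_windows_ignored(self):
        train = build_train("behavior_loom", seed=0)
        recs = self._records_with_escapes(train, escaping_fish=set())
        # escape in the dead time between stimuli must not count
        gap_second = int(train.events[0].end_s) + 2
        recs[0].bins_mm[gap_second] = 60.0
        curve = escape_probability(recs, train)
        assert np.all(curve.p == 0.0)

    def test_estimates_match_binomial_truth(self):
        train = build_train("behavior_checker", seed=2)
        p_true = 0.4
        recs = generate_behavior(
            200, train, ConstantEscapeModel(p=p_true), seed=3
        )
        curve = escape_probability(recs, train)
        se = np.sqrt(p_true * (1 - p_true) / 200)
        assert np.all(np.abs(curve.p - p_true) < 4 * se)


def _ats_permutation_pvalue(data, n_perm=2000, seed=0):
    """Permutation oracle: shuffle time points within each subject."""
    rng = np.random.default_rng(seed)
    obs = ats_habituation(*data.T).statistic
    n, T = data.shape
    count = 0
    for _ in range(n_perm):
        perm = data.copy()
        for i in range(n):
            perm[i] = perm[i, rng.permutation(T)]
        if ats_habituation(*perm.T).statistic >= obs - 1e-12:
            count += 1
    return count / n_perm


class TestHabituationAts:
    def test_identical_timepoints_give_p_one(self):
        x = np.ones(15)
        res = ats_habituation(x, x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_total_response_loss_is_significant(self):
        res = ats_habituation(np.ones(20), np.zeros(20), np.zeros(20))
        assert res.p_value < 0.01

    def test_agrees_with_permutation_oracle(self, rng):
        # moderate effect so neither p is degenerate
        data = rng.normal(size=(12, 3))
        data[:, 0] += 0.8
        p_ats = ats_habituation(*data.T).p_value
        p_perm = _ats_permutation_pvalue(data.copy(), n_perm=4000, seed=1)
        assert abs(p_ats - p_perm) < 0.05

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ats_habituation(np.array([1.0]), np.array([0.0]), np.array([0.0]))

    def test_binary_data_supported(self, rng):
        a = (rng.random(25) < 0.9).astype(float)
        b = (rng.random(25) < 0.2).astype(float)
        res = ats_habituation(a, b, b)
        assert res.p_value < 0.05


def _mwu_enumeration_pvalue(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled data."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    nx = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        ranks = rankdata(pooled)
        rx = sum(ranks[i] for i in ix)
        return rx - nx * (nx + 1) / 2

    obs = u_stat(range(nx))
    u_all = []
    for ix in itertools.combinations(idx, nx):
        u_all.append(u_stat(ix))
    u_all = np.array(u_all)
    # two-sided: twice the smaller tail, capped at 1
    p_lo = np.mean(u_all <= obs + 1e-12)
    p_hi = np.mean(u_all >= obs - 1e-12)
    return min(1.0, 2.0 * min(p_lo, p_hi))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p_raw, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p_raw == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p_raw, p_bonf = mann_whitney_u([2, 2, 5], [2, 2, 5])
        assert p_raw == 1.0
        assert p_bonf == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        _, p_raw, p_bonf = mann_whitney_u([1, 2, 3], [4, 5, 6], n_comparisons=8)
        assert p_bonf == pytest.approx(min(1.0, p_raw * 8))
        _, _, capped = mann_whitney_u([1, 2, 2], [2, 2, 3], n_comparisons=1000)
        assert capped == 1.0

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 2, 3, 4], [3, 5, 6, 7, 8]),
            ([0, 0, 1, 1], [1, 1, 1, 0]),  # heavy ties
            ([1.5, 2.5], [0.5, 3.5, 4.5]),
        ],
    )
    def test_matches_enumeration_oracle(self, x, y):
        _, p_raw, _ = mann_whitney_u(x, y)
        p_exact = _mwu_enumeration_pvalue(np.array(x, float), np.array(y, float))
        assert p_raw == pytest.approx(p_exact, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFitEscapeDecay:
    def test_noiseless_recovery(self):
        k = np.arange(1, 31, dtype=float)
        p = np.clip(0.9 * np.exp(-0.2 * k), 0, 1)
        curve = EscapeCurve(p=p, n_fish=100)
        fit = fit_escape_decay(curve)
        assert fit.Y0 == pytest.approx(0.9, abs=1e-6)
        assert fit.K == pytest.approx(0.2, abs=1e-6)

    def test_all_zero_curve_not_identifiable(self):
        curve = EscapeCurve(p=np.zeros(30), n_fish=10)
        fit = fit_escape_decay(curve)
        assert fit.Y0 == 0.0
        assert not fit.identifiable

    def test_linear_tail_fit(self):
        k = np.arange(1, 31, dtype=float)
        p = np.clip(0.9 * np.exp(-0.2 * k), 0, 1)
        p[20:] = 0.5 - 0.01 * (k[20:] - 20)
        fit = fit_escape_decay(EscapeCurve(p=p, n_fish=50))
        assert fit.slope == pytest.approx(-0.01, abs=1e-9)

    def test_noisy_binomial_recovery(self, rng):
        k = np.arange(1, 31, dtype=float)
        truth = 0.8 * np.exp(-0.25 * k)
        p = rng.binomial(100, np.clip(truth, 0, 1)) / 100
        fit = fit_escape_decay(EscapeCurve(p=p, n_fish=100))
        assert abs(fit.K - 0.25) / 0.25 < 0.25
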