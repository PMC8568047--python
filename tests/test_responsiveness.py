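import numpy as np
import pandas as pd
import pytest

from habitrace.responsiveness import (
    event_design,
    expected_noise_max,
    fit_range_for_events,
    group_mean_responses,
    max_response,
    noise_sd_estimate,
    regress_design,
    regress_roi,
    select_responsive,
    zscore_pooled,
    zscore_trace,
)
from habitrace.stimulus import Regressor, StimulusEvent, build_regressor, build_train


class TestZScore:
    def test_closed_form_three_points(self):
        z = zscore_trace(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])  # sample sd (n-1)
        z_pop = zscore_trace(np.array([1.0, 2.0, 3.0]), ddof=0)
        assert np.allclose(z_pop, [-1.2247448, 0.0, 1.2247448])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=200)
        assert np.allclose(zscore_trace(x), zscore_trace(5.0 * x - 3.0))

    def test_mean_zero_unit_sd(self, rng):
        z = zscore_trace(rng.normal(2.0, 7.0, size=500))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_trace(np.full(10, 3.3))

    def test_matrix_mode_drops_constant_rows(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 50)))
        mat.iloc[1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_pooled(mat)
        assert list(z.index) == [0, 2]
        assert np.allclose(z.mean(axis=1), 0.0)

    def test_pooled_mode_preserves_offsets(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 100)))
        mat.iloc[0] += 10.0
        z = zscore_pooled(mat, per_roi=False)
        # the offset row stays above the others
        assert z.iloc[0].mean() > z.iloc[1].mean() + 1.0


class TestRegression:
    def _regressor(self):
        train = build_train("imaging1_loom", seed=0)
        return build_regressor(train, {"loom"})

    def test_perfect_fit(self):
        reg = self._regressor()
        assert regress_roi(reg.samples.copy(), reg) == pytest.approx(1.0)

    def test_affine_invariance_of_r2(self):
        reg = self._regressor()
        assert regress_roi(3.0 * reg.samples + 7.0, reg) == pytest.approx(1.0)

    def test_white_noise_has_tiny_r2(self, rng):
        reg = self._regressor()
        r2s = [regress_roi(rng.normal(size=len(reg)), reg) for _ in range(50)]
        assert np.mean(np.array(r2s) < 0.05) > 0.95

    def test_equals_squared_pearson(self, rng):
        # independent oracle: r² of simple OLS = squared correlation
        reg = self._regressor()
        trace = reg.samples + rng.normal(0, 0.5, size=len(reg))
        r = np.corrcoef(trace, reg.samples)[0, 1]
        assert regress_roi(trace, reg) == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_regressor_rejected(self):
        reg = Regressor(samples=np.zeros(100))
        with pytest.raises(ValueError, match="variance"):
            regress_roi(np.random.default_rng(0).normal(size=100), reg)

    def test_fit_range_restricts_regression(self, rng):
        reg = self._regressor()
        n = len(reg)
        trace = np.copy(reg.samples)
        trace[: n // 4] = rng.normal(size=n // 4)  # corrupt outside the range
        fit_range = np.arange(n // 2, n)
        assert regress_roi(trace, reg, fit_range) == pytest.approx(1.0)

    def test_design_matrix_path_matches_single(self, rng):
        reg = self._regressor()
        trace = reg.samples + rng.normal(0, 1.0, size=len(reg))
        r2_single = regress_roi(trace, reg)
        r2_multi = regress_design(trace, reg.samples.reshape(-1, 1))[0]
        assert r2_single == pytest.approx(r2_multi, abs=1e-10)

    def test_event_design_absorbs_habituating_amplitudes(self, rng):
        train = build_train("imaging3_component", seed=0)
        comp = [0, 1, 2, 3, 14, 15, 16, 17]
        design = event_design(train, comp, 3.5, 2.0)
        fr = fit_range_for_events(train, comp, 2.0)
        weights = np.exp(-0.7 * np.arange(8))
        trace = design @ weights + rng.normal(0, 0.05, size=len(design))
        r2 = regress_design(trace, design, fr)[0]
        assert r2 > 0.99


class TestSelectResponsive:
    def test_all_equal_r2_selects_none(self):
        res = select_responsive(np.full(10, 0.4))
        assert res.threshold == pytest.approx(0.4)
        assert res.n_responsive == 0  # strict inequality

    def test_hand_computed_threshold(self):
        # median 0.15; sample SD of {0, .1, .2, .9} = 0.40311...
        vals = np.array([0.0, 0.1, 0.2, 0.9])
        res = select_responsive(vals)
        sd = np.std(vals, ddof=1)
        assert res.threshold == pytest.approx(0.15 + 2 * sd)
        assert list(res.responsive) == [False, False, False, False]
        # 0.9 < 0.15 + 0.806 = 0.956, so even the top ROI fails here

    def test_clear_bimodal_distribution(self):
        vals = np.r_[np.full(95, 0.01), np.full(5, 0.95)]
        res = select_responsive(vals)
        assert res.n_responsive == 5

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            select_responsive(np.array([0.5]))


class TestMaxResponse:
    def _event(self):
        return StimulusEvent(kind="loom", onset_s=50.0)

    def test_constant_trace_gives_zero(self):
        z = np.zeros(400)
        assert max_response(z, self._event(), rate_hz=2.0) == 0.0

    def test_baseline_subtraction(self):
        z = np.zeros(400)
        rate = 2.0
        ev = self._event()
        z[int((ev.onset_s - 5) * rate): int(ev.onset_s * rate)] = 1.0
        z[int(ev.onset_s * rate) + 4] = 3.0
        assert max_response(z, ev, rate_hz=rate) == pytest.approx(2.0)

    def test_window_spans_expansion_and_fade(self):
        z = np.zeros(400)
        rate = 2.0
        ev = self._event()
        # peak during the fade still counts
        z[int((ev.onset_s + ev.expand_s + 5) * rate)] = 4.0
        assert max_response(z, ev, rate_hz=rate) == pytest.approx(4.0)

    def test_truncated_baseline_warns(self):
        ev = StimulusEvent(kind="dim", onset_s=1.0)
        z = np.zeros(200)
        with pytest.warns(UserWarning, match="truncated"):
            max_response(z, ev, rate_hz=2.0, baseline_s=5.0)

    def test_kernel_peak_close_to_injected_amplitude(self):
        # noiseless transient: peak of the kernel-convolved pulse relative to
        # the per-sample amplitude follows the geometric sum of the kernel
        from habitrace.stimulus import StimulusTrain, _exp_kernel

        rate, tau = 2.0, 3.5
        ev = StimulusEvent(kind="loom", onset_s=50.0)
        train = StimulusTrain((ev,), (), 120.0)
        n = int(120 * rate)
        t = np.arange(n) / rate
        ind = np.zeros(n)
        ind[(t >= ev.onset_s) & (t < ev.onset_s + ev.expand_s)] = 1.0
        sig = np.convolve(ind, _exp_kernel(tau, rate))[:n]
        expected_peak = np.sum(np.exp(-np.arange(10) / (tau * rate)))
        assert max_response(sig, ev, rate) == pytest.approx(expected_peak, rel=1e-6)


class TestNoiseEstimate:
    def test_diff_mad_recovers_white_noise_sd(self, rng):
        x = rng.normal(0, 0.7, size=5000)
        assert noise_sd_estimate(x) == pytest.approx(0.7, rel=0.05)

    def test_slow_signal_does_not_inflate_estimate(self, rng):
        t = np.linspace(0, 20 * np.pi, 5000)
        x = 5.0 * np.sin(0.05 * t) + rng.normal(0, 0.5, size=5000)
        assert noise_sd_estimate(x) == pytest.approx(0.5, rel=0.1)

    def test_expected_max_grows_with_window(self):
        assert expected_noise_max(100, 1.0) > expected_noise_max(10, 1.0) > 0
        assert expected_noise_max(40, 2.0) == pytest.approx(
            2.0 * expected_noise_max(40, 1.0)
        )


class TestGroupMeans:
    def test_single_fish_equals_fish_mean(self):
        resp = pd.DataFrame({1: [1.0, 3.0], 2: [2.0, 4.0]}, index=[10, 11])
        fish = pd.Series({10: 0, 11: 0})
        out = group_mean_responses(resp, fish)
        assert out[1] == pytest.approx(2.0)
        assert out[2] == pytest.approx(3.0)

    def test_fish_weighted_not_roi_weighted(self):
        # fish 0 has three ROIs at 1.0; fish 1 has one ROI at 3.0
        resp = pd.DataFrame({1: [1.0, 1.0, 1.0, 3.0]}, index=[0, 1, 2, 3])
        fish = pd.Series({0: 0, 1: 0, 2: 0, 3: 1})
        out = group_mean_responses(resp, fish)
        assert out[1] == pytest.approx(2.0)  # (1 + 3) / 2, not 1.5

    def test_roi_order_invariance(self, rng):
        resp = pd.DataFrame(rng.normal(size=(6, 3)), index=list(range(6)))
        fish = pd.Series([0, 0, 1, 1, 2, 2], index=list(range(6)))
        perm = rng.permutation(6)
        out1 = group_mean_responses(resp, fish)
        out2 = group_mean_responses(resp.iloc[perm], fish)
        assert np.allclose(out1, out2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_mean_responses(pd.DataFrame(), pd.Series(dtype=float))
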