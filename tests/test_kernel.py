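"""The shifted-gamma kernel, convolution prediction, and scoring."""

import numpy as np
import pytest
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from nvctf import (
    Prediction,
    TFParams,
    UniformSeries,
    convolve_predict,
    evaluate_tf,
    pearson,
    rescale_amplitude,
    sum_squared_residuals,
    tf_peak_time,
)
from nvctf.errors import (
    DegenerateScaleError,
    InvalidInputError,
    InvalidParameterError,
    ModeAtOnsetError,
    UndefinedCorrelationError,
)

from conftest import random_valid_params, series


class TestEvaluateTF:
    def test_standard_kernel_peaks_at_0_9_s(self, standard_params):
        grid = np.arange(0.0, 10.0005, 0.001)
        values = evaluate_tf(standard_params, grid)
        assert round(grid[np.argmax(values)], 1) == 0.9

    def test_zero_at_and_before_time_shift(self, standard_params):
        grid = np.array([-1.0, 0.0, 0.1, standard_params.p3])
        np.testing.assert_array_equal(evaluate_tf(standard_params, grid), 0.0)

    def test_matches_independent_gamma_pdf(self, standard_params):
        # oracle: scipy's gamma density (independent log-gamma implementation)
        t = 0.87
        expected = standard_params.p4 * gamma_dist.pdf(
            t - standard_params.p3, a=standard_params.p1, scale=1.0 / standard_params.p2
        )
        got = evaluate_tf(standard_params, np.array([t]))[0]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_random_kernels_match_gamma_pdf(self, rng):
        grid = np.linspace(0.0, 30.0, 400)
        for _ in range(20):
            p = random_valid_params(rng)
            expected = p.p4 * gamma_dist.pdf(grid - p.p3, a=p.p1, scale=1.0 / p.p2)
            np.testing.assert_allclose(evaluate_tf(p, grid), expected, rtol=1e-9, atol=1e-300)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            TFParams(-1.0, 0.5, 0.1, 1.0)
        with pytest.raises(InvalidParameterError):
            TFParams(1.3, 0.0, 0.1, 1.0)

    def test_integral_equals_amplitude(self, rng):
        # the gamma density integrates to 1, so the kernel integrates to p4
        from scipy.integrate import quad

        for _ in range(10):
            p = random_valid_params(rng)
            hi = p.p3 + (40.0 + 10.0 * p.p1) / p.p2
            val, _ = quad(lambda t: evaluate_tf(p, np.array([t]))[0], p.p3, hi, limit=200)
            assert val == pytest.approx(p.p4, rel=1e-6)


class TestPeakTime:
    def test_closed_form_vs_grid_argmax(self, standard_params):
        assert tf_peak_time(standard_params) == pytest.approx(0.87)
        grid = np.arange(0.0, 10.0, 0.001)
        argmax = grid[np.argmax(evaluate_tf(standard_params, grid))]
        assert abs(argmax - tf_peak_time(standard_params)) <= 0.001

    def test_simple_value(self):
        assert tf_peak_time(TFParams(2.0, 1.0, 1e-9, 1.0)) == pytest.approx(1.0)

    def test_time_shift_translates_peak(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            base = TFParams(p.p1, p.p2, 1e-12, p.p4)
            assert tf_peak_time(p) - tf_peak_time(base) == pytest.approx(p.p3)

    def test_agreement_with_argmax_for_random_kernels(self, rng):
        grid = np.arange(0.0, 120.0, 0.001)
        for _ in range(100):
            p = random_valid_params(rng)
            argmax = grid[np.argmax(evaluate_tf(p, grid))]
            assert abs(argmax - tf_peak_time(p)) <= 0.001 + 1e-9

    def test_mode_at_onset_rejected(self):
        with pytest.raises(ModeAtOnsetError):
            tf_peak_time(TFParams(0.9, 1.0, 0.1, 1.0))


def _impulse(t0=0.0, dt=0.05, n=600, at=0):
    values = np.zeros(n)
    values[at] = 1.0 / dt
    return UniformSeries(t0, dt, values)


class TestConvolvePredict:
    def test_impulse_response_identity(self, standard_params):
        sig = _impulse()
        pred = convolve_predict(sig, standard_params, sig)
        expected = evaluate_tf(standard_params, sig.times)
        assert np.max(np.abs(pred.series.values - expected)) < 1e-9

    def test_zero_signal_zero_prediction(self, standard_params):
        sig = UniformSeries(0.0, 0.05, np.zeros(200))
        pred = convolve_predict(sig, standard_params, sig)
        np.testing.assert_array_equal(pred.series.values, 0.0)

    def test_unit_step_matches_incomplete_gamma_closed_form(self, standard_params):
        # y(t) = p4 * P(p1, p2 (t - s0 - p3)), P the regularized lower
        # incomplete gamma
        dt, s0 = 0.05, 2.0
        n = 600
        times = dt * np.arange(n)
        sig = UniformSeries(0.0, dt, (times >= s0).astype(float))
        pred = convolve_predict(sig, standard_params, sig).series.values
        u = standard_params.p2 * (times - s0 - standard_params.p3)
        expected = standard_params.p4 * gammainc(standard_params.p1, np.clip(u, 0, None))
        assert np.max(np.abs(pred - expected)) <= 0.01 * np.max(np.abs(expected))

    def test_linearity(self, standard_params, rng):
        dt = 0.05
        x = UniformSeries(0.0, dt, rng.normal(size=300))
        y = UniformSeries(0.0, dt, rng.normal(size=300))
        a, b = 1.7, -0.4
        combo = UniformSeries(0.0, dt, a * x.values + b * y.values)
        px = convolve_predict(x, standard_params, x).series.values
        py = convolve_predict(y, standard_params, y).series.values
        pc = convolve_predict(combo, standard_params, combo).series.values
        np.testing.assert_allclose(pc, a * px + b * py, atol=1e-12)

    def test_causality(self, standard_params, rng):
        # perturbing a late sample leaves earlier outputs untouched
        dt = 0.05
        values = rng.normal(size=400)
        base = UniformSeries(0.0, dt, values)
        k = 300
        perturbed = UniformSeries(0.0, dt, values + 5.0 * (np.arange(400) == k))
        pb = convolve_predict(base, standard_params, base).series.values
        pp = convolve_predict(perturbed, standard_params, base).series.values
        np.testing.assert_array_equal(pb[:k], pp[:k])

    def test_empty_signal_rejected(self, standard_params):
        with pytest.raises(InvalidInputError):
            UniformSeries(0.0, 0.05, np.array([]))


class TestRescaleAmplitude:
    def _pred_and_obs(self, standard_params, factor):
        sig = _impulse(n=400)
        pred = convolve_predict(sig, standard_params, sig)
        observed = pred.series.with_values(factor * pred.series.values)
        return pred, observed

    def test_identical_series_scale_one(self, standard_params):
        pred, obs = self._pred_and_obs(standard_params, 1.0)
        out = rescale_amplitude(pred, obs, stimulus_onset=1.0)
        assert out.scale == pytest.approx(1.0, abs=1e-6)

    def test_doubled_observation_matches_closed_form(self, standard_params):
        pred, obs = self._pred_and_obs(standard_params, 2.0)
        out = rescale_amplitude(pred, obs, stimulus_onset=1.0)
        # oracle: least-squares scale k = sum(p*o)/sum(p^2) over the window
        times = pred.series.times
        m = (times >= 3.0) & (times <= 9.0)
        p, o = pred.series.values[m], obs.values[m]
        assert out.scale == pytest.approx(np.sum(p * o) / np.sum(p * p), abs=1e-6)
        assert out.scale == pytest.approx(2.0, abs=1e-6)

    def test_pearson_unchanged_by_rescaling(self, standard_params, rng):
        sig = UniformSeries(0.0, 0.05, np.abs(rng.normal(size=400)))
        pred = convolve_predict(sig, standard_params, sig)
        obs = sig.with_values(pred.series.values + rng.normal(0, 0.1, 400))
        before = pearson(pred.series, obs)
        after = pearson(rescale_amplitude(pred, obs, 1.0).series, obs)
        assert after == pytest.approx(before, abs=1e-12)

    def test_zero_prediction_window_rejected(self, standard_params):
        pred = Prediction(UniformSeries(0.0, 0.05, np.zeros(400)))
        obs = UniformSeries(0.0, 0.05, np.ones(400))
        with pytest.raises(DegenerateScaleError):
            rescale_amplitude(pred, obs, stimulus_onset=1.0)


class TestPearson:
    def test_self_correlation_is_one(self):
        a = series([1.0, 2.0, 4.0, 3.0])
        assert pearson(a, a) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        a = series([1.0, 2.0, 4.0, 3.0])
        assert pearson(a, a.with_values(-a.values)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # direct formula on (1,2,3,4) vs (1,3,2,4) gives 0.8
        a, b = series([1.0, 2.0, 3.0, 4.0]), series([1.0, 3.0, 2.0, 4.0])
        assert pearson(a, b) == pytest.approx(0.8)

    def test_scale_and_offset_invariance(self, rng):
        x = series(rng.normal(size=60))
        y = series(rng.normal(size=60))
        assert pearson(x.with_values(3.0 * x.values + 2.0), y) == pytest.approx(
            pearson(x, y), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(series([1.0, 1.0, 1.0]), series([1.0, 2.0, 3.0]))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson(series([1.0, 2.0, 3.0], dt=1.0), series([1.0, 2.0, 3.0], dt=0.5))


class TestSumSquaredResiduals:
    def test_zero_for_identical(self):
        a = series([1.0, 2.0, 3.0])
        assert sum_squared_residuals(a, a) == 0.0

    def test_constant_offset(self):
        a = series(np.zeros(7))
        b = series(np.full(7, 0.5))
        assert sum_squared_residuals(a, b) == pytest.approx(7 * 0.25)

    def test_matches_elementwise_loop(self, rng):
        a = series(rng.normal(size=30))
        b = series(rng.normal(size=30))
        expected = sum((x - y) ** 2 for x, y in zip(a.values, b.values))
        assert sum_squared_residuals(a, b) == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            sum_squared_residuals(series(np.zeros(3)), series(np.zeros(4)))
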