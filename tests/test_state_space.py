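import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoact.state_space import FitConfig, SSParams, cost, fit, forecast, rmse


def closed_form(params, la, y1):
    """Independent superposition oracle:
    y[t] = T_min + (y1-T_min) r^t + a1 * sum_{k<t} r^(t-1-k) A[k], r = 1+a2."""
    r = 1.0 + params.a2
    n = len(la)
    out = np.empty(n)
    for t in range(n):
        conv = sum(r ** (t - 1 - k) * la[k] for k in range(t))
        out[t] = params.t_min + (y1 - params.t_min) * r**t + params.a1 * conv
    return out


class TestForecast:
    def test_fixed_point_at_t_min(self):
        p = SSParams(0.0016, -0.02, 35.0)
        y = forecast(p, np.zeros(100), 35.0).values
        np.testing.assert_allclose(y, 35.0, atol=1e-12)

    def test_geometric_decay_closed_form(self):
        p = SSParams(0.0016, -0.02, 35.0)
        y = forecast(p, np.zeros(200), 36.0).values
        expected = 35.0 + 0.98 ** np.arange(200)
        np.testing.assert_allclose(y, expected, atol=1e-9)
        assert y[100] - 35.0 == pytest.approx(0.98**100, rel=1e-12)

    def test_constant_activity_converges_to_fixed_point(self):
        # equilibrium offset solves a1*A + a2*(y*-T_min) = 0 -> 0.8 degC
        p = SSParams(0.0016, -0.02, 35.0)
        y = forecast(p, np.full(20000, 10.0), 35.0).values
        assert y[-1] == pytest.approx(35.0 + 0.8, abs=1e-9)

    def test_output_length_matches_activity(self):
        p = SSParams(0.001, -0.01, 35.0)
        assert len(forecast(p, np.zeros(500), 36.0)) == 500

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            forecast(SSParams(0.001, -0.01, 35.0), np.zeros(10), np.nan)

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_superposition_oracle(self, data):
        a1 = data.draw(st.floats(0.0, 0.01))
        a2 = data.draw(st.floats(-0.5, -0.001))
        t_min = data.draw(st.floats(33.0, 37.0))
        y1 = data.draw(st.floats(33.0, 39.0))
        n = data.draw(st.integers(2, 40))
        la = np.array(data.draw(st.lists(
            st.floats(0, 50), min_size=n, max_size=n)))
        p = SSParams(a1, a2, t_min)
        np.testing.assert_allclose(
            forecast(p, la, y1).values, closed_form(p, la, y1),
            rtol=1e-9, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_bounded_and_monotone_in_activity(self, seed):
        rng = np.random.default_rng(seed)
        p = SSParams(rng.uniform(1e-4, 3e-3), rng.uniform(-0.1, -0.005),
                     rng.uniform(34, 36))
        la = rng.gamma(2, 10, 2000) * (rng.random(2000) < 0.4)
        y1 = p.t_min + rng.uniform(0, 2)
        y = forecast(p, la, y1).values
        bound = p.t_min + max(abs(y1 - p.t_min), p.a1 * la.max() / abs(p.a2)) + 1e-9
        assert np.all(y <= bound) and np.all(y >= p.t_min - 1e-9)
        # pointwise-larger activity never yields a smaller forecast
        y_hi = forecast(p, la + 1.0, y1).values
        assert np.all(y_hi >= y - 1e-12)


class TestCostRmse:
    def test_perfect_prediction_zero(self):
        assert cost([1.0, 2.0], [1.0, 2.0], [0.5, 0.5], 0.0) == 0.0

    def test_direct_arithmetic(self):
        assert cost([1, 2], [0, 0], [1, 1], 0.5) == pytest.approx(6.0)

    def test_monotone_in_lambda(self):
        c = [cost([1, 2], [0, 1], [2, 3], lam) for lam in (0.0, 0.5, 1.0, 5.0)]
        assert c == sorted(c)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cost([1, 2], [1], [0], 0.0)

    @pytest.mark.parametrize("obs, pred, expected", [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([37.0, 36.0], [36.5, 35.5], 0.5),
        ([3.0, -4.0], [0.0, 0.0], np.sqrt(12.5)),
    ])
    def test_rmse_values(self, obs, pred, expected):
        assert rmse(obs, pred) == pytest.approx(expected)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestFit:
    def test_noiseless_recovery_within_one_percent(self, rng, nominal_params):
        la = rng.gamma(2, 10, 10000) * (rng.random(10000) < 0.3)
        truth = nominal_params
        cbt = forecast(truth, la, 36.0).values
        res = fit([(cbt, la)])
        assert res.converged
        for got, want in zip(res.params.as_array(), truth.as_array()):
            assert abs(got - want) / abs(want) < 0.01

    def test_noise_floor(self, rng, nominal_params):
        la = rng.gamma(2, 10, 10000) * (rng.random(10000) < 0.3)
        cbt = forecast(nominal_params, la, 36.0).values + rng.normal(0, 0.1, 10000)
        res = fit([(cbt, la)])
        assert res.rmse == pytest.approx(0.1, rel=0.05)

    def test_degenerate_constant_record(self):
        cbt = np.full(500, 36.5)
        res = fit([(cbt, np.zeros(500))])
        assert res.params.t_min == pytest.approx(36.5, abs=1e-3)
        assert res.rmse < 1e-3

    def test_multisegment_each_restarts_from_own_first_sample(self, rng, nominal_params):
        la1 = rng.gamma(2, 10, 3000) * (rng.random(3000) < 0.3)
        la2 = rng.gamma(2, 10, 3000) * (rng.random(3000) < 0.3)
        c1 = forecast(nominal_params, la1, 36.5).values
        c2 = forecast(nominal_params, la2, 35.2).values
        res = fit([(c1, la1), (c2, la2)])
        assert res.n_segments == 2
        # each segment's first prediction pins to its own observed start
        assert res.predicted.values[0] == pytest.approx(36.5)
        assert res.predicted.values[3000] == pytest.approx(35.2)
        for got, want in zip(res.params.as_array(), nominal_params.as_array()):
            assert abs(got - want) / abs(want) < 0.01

    def test_fit_is_deterministic(self, rng, nominal_params):
        la = rng.gamma(2, 10, 4000) * (rng.random(4000) < 0.3)
        cbt = forecast(nominal_params, la, 36.0).values + rng.normal(0, 0.1, 4000)
        r1 = fit([(cbt, la)], FitConfig())
        r2 = fit([(cbt, la)], FitConfig())
        np.testing.assert_array_equal(r1.params.as_array(), r2.params.as_array())

    def test_fitted_model_is_stable(self, small_cohort):
        records, _ = small_cohort
        rec = records[0]
        res = fit([(rec.cbt.values, rec.la.values)])
        assert res.params.stable
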