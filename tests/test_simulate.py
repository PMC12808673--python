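import numpy as np
import pytest

from thermoact.io_preprocess import MINUTES_PER_DAY, complete_days
from thermoact.simulate import (
    SexParams, SimulationConfig, boundary_regime_config,
    generate_cbt, generate_la, make_cohort,
)
from thermoact.state_space import SSParams, fit, forecast
from thermoact.simulate import _dark_mask


class TestGenerateLA:
    def test_zero_start_probability_means_no_activity(self):
        cfg = SimulationConfig(p_start_dark=0.0, p_start_light=0.0, days=2)
        la = generate_la(cfg, 0)
        assert la.values.sum() == 0

    def test_dark_phase_activity_dominates(self):
        cfg = SimulationConfig(days=4)
        means_d, means_l = [], []
        for seed in range(5):
            la = generate_la(cfg, seed)
            dark = _dark_mask(cfg, cfg.n_minutes)
            means_d.append(la.values[dark].mean())
            means_l.append(la.values[~dark].mean())
        assert np.mean(means_d) > 2 * np.mean(means_l)

    def test_deterministic_per_seed(self):
        cfg = SimulationConfig(days=1)
        np.testing.assert_array_equal(generate_la(cfg, 7).values,
                                      generate_la(cfg, 7).values)

    def test_nonnegative_counts(self):
        la = generate_la(SimulationConfig(days=2), 3)
        assert (la.values >= 0).all()


class TestGenerateCBT:
    def test_noiseless_rest_is_geometric_decay(self):
        la = generate_la(SimulationConfig(
            p_start_dark=0.0, p_start_light=0.0, days=1), 0)
        p = SSParams(0.0016, -0.02, 35.0)
        cbt = generate_cbt(la, p, y1_offset=1.0)
        expected = 35.0 + 0.98 ** np.arange(MINUTES_PER_DAY)
        np.testing.assert_allclose(cbt.values, expected, atol=1e-9)

    def test_matches_forecast_when_deterministic(self, rng, nominal_params):
        cfg = SimulationConfig(days=2)
        la = generate_la(cfg, 5)
        cbt = generate_cbt(la, nominal_params, y1_offset=0.5)
        pred = forecast(nominal_params, la, nominal_params.t_min + 0.5)
        np.testing.assert_allclose(cbt.values, pred.values, atol=1e-9)

    def test_unstable_dynamics_rejected(self):
        la = generate_la(SimulationConfig(days=1), 0)
        with pytest.raises(ValueError, match="unstable"):
            generate_cbt(la, SSParams(0.001, -2.5, 35.0))

    def test_fit_recovers_generative_parameters(self, nominal_params):
        cfg = SimulationConfig(days=7)
        la = generate_la(cfg, 11)
        cbt = generate_cbt(la, nominal_params, seed=11)
        res = fit([(cbt.values, la.values)])
        for got, want in zip(res.params.as_array(), nominal_params.as_array()):
            assert abs(got - want) / abs(want) < 0.01

    def test_endogenous_component_survives_into_residuals(self, nominal_params):
        cfg = SimulationConfig(days=6)
        la = generate_la(cfg, 21)
        cbt = generate_cbt(la, nominal_params, seed=21, noise_sd=0.05,
                           endogenous=[(1440.0, 0.3, 0.0)])
        res = fit([(cbt.values, la.values)])
        r = res.residuals.values
        # fold residuals by day: a consistent daily shape remains
        daily = r.reshape(-1, MINUTES_PER_DAY).mean(axis=0)
        assert daily.max() - daily.min() > 0.05


class TestMakeCohort:
    def test_dimensions_and_determinism(self):
        cfg = SimulationConfig(n_male=2, n_female=2, days=6, seed=9)
        rec1, truth1 = make_cohort(cfg)
        rec2, _ = make_cohort(SimulationConfig(n_male=2, n_female=2, days=6, seed=9))
        assert len(rec1) == 4
        assert all(r.n_minutes == 6 * MINUTES_PER_DAY for r in rec1)
        for a, b in zip(rec1, rec2):
            np.testing.assert_array_equal(a.cbt.values, b.cbt.values)
            np.testing.assert_array_equal(a.la.values, b.la.values)
            assert a.estrous_days == b.estrous_days

    def test_default_cohort_shape(self):
        cfg = SimulationConfig(seed=0)
        assert cfg.n_male == 13 and cfg.n_female == 13
        assert cfg.n_minutes == 20160

    def test_estrous_and_unlabeled_day_bookkeeping(self):
        records, truth = make_cohort(SimulationConfig(n_male=1, n_female=3, seed=4))
        for rec in records:
            n_days = len(complete_days(rec))
            if rec.sex == "M":
                assert rec.estrous_days == frozenset()
            else:
                assert len(rec.estrous_days) == 4
                days = sorted(rec.estrous_days)
                assert days == list(range(days[0], days[0] + 4))
                assert 0 not in rec.estrous_days  # day 0 stays unlabeled
                assert len(rec.nonestrous_days(n_days)) == 9

    def test_cbt_stays_within_physical_envelope(self):
        records, truth = make_cohort(SimulationConfig(n_male=2, n_female=2, days=6, seed=2))
        for rec in records:
            p = truth.params[rec.mouse_id]
            hi = p.t_min + p.a1 * rec.la.values.max() / abs(p.a2) + 1.0
            assert rec.cbt.values.min() > p.t_min - 1.0
            assert rec.cbt.values.max() < hi

    def test_boundary_regime_is_parameter_homogeneous(self):
        records, truth = make_cohort(boundary_regime_config(3, n_male=2, n_female=1, days=2))
        params = {(p.a1, p.a2, p.t_min) for p in truth.params.values()}
        assert len(params) == 1
        assert truth.config.noise_sd == 0.0 and truth.config.process_noise_sd > 0
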