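"""Forward-simulation contracts: closed-form limits, route-combination
equivalences, death mechanisms, and backend agreement."""

import numpy as np
import pytest

from bufferguts import (
    ExposureProfile,
    ModelSpec,
    ParamSet,
    default_grid,
    predict_scenario,
    simulate,
    survival_it,
    survival_sd,
)
from conftest import random_instance


class TestStates:
    def test_no_exposure_no_background_survival_is_one(self):
        spec = ModelSpec("CA", "SD", 1)
        params = ParamSet(kd=(0.5,), z=1.0, kk=0.1, hb=0.0)
        profile = ExposureProfile(1, "u", ())
        grid = default_grid([profile], horizon=5.0)
        traj = simulate(spec, params, [profile], grid)
        assert np.allclose(traj.S, 1.0)
        assert np.allclose(traj.D, 0.0)

    def test_fast_buffer_limit_recovers_reduced_guts_damage(self):
        # eta -> infinity removes the buffer lag: for constant exposure c the
        # damage tends to the classic scaled-damage form c*(1 - exp(-kd*t)).
        kd, c = 0.5, 2.0
        spec = ModelSpec("CA", "SD", 1, eta=1e4)
        params = ParamSet(kd=(kd,), z=0.1, kk=0.1)
        profile = ExposureProfile(1, "u", ((0.0, 10.0, c),))
        grid = default_grid([profile], horizon=10.0)
        traj = simulate(spec, params, [profile], grid)
        exact = c * (1.0 - np.exp(-kd * grid))
        # scale-relative everywhere; pointwise-relative once damage has built up
        assert np.max(np.abs(traj.D - exact)) / exact.max() < 1e-3
        late = grid >= 0.25
        assert np.max(np.abs(traj.D[late] - exact[late]) / exact[late]) < 1e-3

    def test_da_with_shared_kinetics_equals_ca(self, contact_pulse, oral_windows, two_route_grid):
        # with one shared dominant rate constant the order of weighted
        # summation (buffers vs damages) does not matter
        profiles = [contact_pulse, oral_windows]
        ca = simulate(
            ModelSpec("CA", "SD", 2),
            ParamSet(kd=(0.9,), w=(1.0, 5.0), z=0.01, kk=1.0),
            profiles,
            two_route_grid,
        )
        da = simulate(
            ModelSpec("DA", "SD", 2),
            ParamSet(kd=(0.9, 0.9), w=(1.0, 5.0), z=0.01, kk=1.0),
            profiles,
            two_route_grid,
        )
        assert np.max(np.abs(ca.D - da.D)) < 1e-8
        assert np.max(np.abs(ca.S - da.S)) < 1e-8

    def test_single_route_ca_equals_da(self, contact_pulse):
        grid = default_grid([contact_pulse], horizon=4.0)
        params = ParamSet(kd=(1.3,), z=0.002, kk=20.0, hb=0.01)
        ca = simulate(ModelSpec("CA", "SD", 1), params, [contact_pulse], grid)
        da = simulate(ModelSpec("DA", "SD", 1), params, [contact_pulse], grid)
        assert np.max(np.abs(ca.D - da.D)) < 1e-10
        assert np.max(np.abs(ca.S - da.S)) < 1e-10

    def test_route_unit_anchoring(self, contact_pulse, oral_windows, two_route_grid):
        # rescaling route-2 exposure by c while dividing w_2 by c leaves
        # damage and survival unchanged (units cancel)
        c = 37.0
        scaled = ExposureProfile(
            2, "other unit", tuple((a, b, lvl * c) for a, b, lvl in oral_windows.segments)
        )
        for combination in ("CA", "DA"):
            n_kd = 1 if combination == "CA" else 2
            base = ParamSet(kd=(0.8,) * n_kd, w=(1.0, 6.0), z=0.01, kk=2.0)
            adj = ParamSet(kd=(0.8,) * n_kd, w=(1.0, 6.0 / c), z=0.01, kk=2.0)
            spec = ModelSpec(combination, "SD", 2)
            t1 = simulate(spec, base, [contact_pulse, oral_windows], two_route_grid)
            t2 = simulate(spec, adj, [contact_pulse, scaled], two_route_grid)
            assert np.allclose(t1.D, t2.D, atol=1e-10)
            assert np.allclose(t1.S, t2.S, atol=1e-10)

    @pytest.mark.parametrize("combination,death", [("CA", "SD"), ("DA", "IT")])
    def test_analytic_matches_numeric_backend(self, combination, death):
        rng = np.random.default_rng(42)
        for _ in range(10):
            spec, params, profiles, grid = random_instance(
                rng, combination=combination, death=death
            )
            ana = simulate(spec, params, profiles, grid, backend="analytic")
            num = simulate(spec, params, profiles, grid, backend="numeric")
            scale = max(ana.D.max(), 1e-12)
            assert np.max(np.abs(ana.D - num.D)) / scale < 1e-6
            assert np.max(np.abs(ana.B - num.B)) / max(ana.B.max(), 1e-12) < 1e-6

    def test_survival_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            combination = rng.choice(["CA", "DA"])
            death = rng.choice(["SD", "IT"])
            spec, params, profiles, grid = random_instance(
                rng, combination=combination, death=death
            )
            traj = simulate(spec, params, profiles, grid)
            assert traj.S[0] == 1.0
            assert np.all(np.diff(traj.S) <= 1e-12)
            assert np.all((traj.S >= 0) & (traj.S <= 1))
            assert np.all(traj.D >= 0)
            assert np.all(traj.B >= -1e-15)

    def test_input_validation(self, contact_pulse):
        spec = ModelSpec("CA", "SD", 2)
        params = ParamSet(kd=(1.0,), w=(1.0, 2.0), z=0.1, kk=1.0)
        grid = np.linspace(0, 2, 10)
        with pytest.raises(ValueError, match="profiles"):
            simulate(spec, params, [contact_pulse], grid)
        with pytest.raises(ValueError, match="negative exposure"):
            ExposureProfile(1, "u", ((0.0, 1.0, -0.5),))
        with pytest.raises(ValueError, match="increasing|start at 0"):
            simulate(spec, params, [contact_pulse, contact_pulse], np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="kd"):
            ParamSet(kd=(0.0,), z=1.0, kk=1.0)


class TestStochasticDeath:
    def test_damage_below_threshold_gives_background_survival(self):
        t = np.linspace(0, 5, 50)
        D = np.full_like(t, 0.5)
        _, S = survival_sd(t, D, z=1.0, kk=3.0, hb=0.02)
        assert np.allclose(S, np.exp(-0.02 * t))

    def test_constant_excess_damage(self):
        t = np.linspace(0, 10, 100)
        D = np.full_like(t, 2.0)  # z + 1
        _, S = survival_sd(t, D, z=1.0, kk=0.1, hb=0.0)
        assert np.allclose(S, np.exp(-0.1 * t), atol=1e-12)

    def test_exact_integral_matches_fine_quadrature(self):
        # piecewise-linear damage crossing the threshold once
        t_nodes = np.array([0.0, 1.0, 3.0, 6.0])
        d_nodes = np.array([0.0, 2.0, 1.5, 0.2])
        z, kk = 1.0, 0.7
        t_fine = np.linspace(0, 6, 100_001)
        d_fine = np.interp(t_fine, t_nodes, d_nodes)
        quad = np.trapezoid(kk * np.maximum(0.0, d_fine - z), t_fine)
        H, S = survival_sd(t_nodes, d_nodes, z=z, kk=kk, hb=0.0)
        assert abs(H[-1] - quad) < 1e-6
        assert abs(S[-1] - np.exp(-quad)) < 1e-6

    def test_negative_inputs_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            survival_sd(t, np.array([0.0, 1.0]), z=-1.0, kk=1.0)
        with pytest.raises(ValueError):
            survival_sd(t, np.array([0.0, -1.0]), z=1.0, kk=1.0)


class TestIndividualTolerance:
    def test_median_damage_halves_survival(self):
        t = np.linspace(0, 4, 30)
        D = np.minimum(t, 2.0)  # reaches alpha = 2 at t = 2, then flat
        S = survival_it(t, D, alpha=2.0, beta=3.0, hb=0.0)
        assert np.allclose(S[t >= 2.0], 0.5)

    def test_zero_damage_gives_background_survival(self):
        t = np.linspace(0, 5, 20)
        S = survival_it(t, np.zeros_like(t), alpha=1.0, beta=2.0, hb=0.03)
        assert np.allclose(S, np.exp(-0.03 * t))

    def test_survival_constant_after_damage_peak(self):
        # running maximum: a pulse followed by decay cannot kill anyone else
        t = np.linspace(0, 10, 201)
        D = np.exp(-((t - 2.0) ** 2))  # peak at t = 2
        S = survival_it(t, D, alpha=0.5, beta=4.0, hb=0.0)
        after = t > 2.0
        assert np.allclose(S[after], S[after][0])
        assert np.all(np.diff(S) <= 1e-15)

    def test_invalid_shape_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            survival_it(t, np.array([0.0, 1.0]), alpha=0.0, beta=1.0)


class TestPredictScenario:
    spec = ModelSpec("CA", "SD", 2)
    params = ParamSet(kd=(0.7,), w=(1.0, 0.02), z=0.002, kk=50.0, hb=0.0)

    def test_zero_exposure_gives_background_survival(self):
        params = ParamSet(kd=(0.7,), w=(1.0, 0.02), z=0.002, kk=50.0, hb=0.05)
        traj = predict_scenario(self.spec, params, 0.0, 0.0, 0.0, 1.0, horizon=5.0)
        assert np.allclose(traj.S, np.exp(-0.05 * traj.times))

    def test_oral_only_scenario_matches_plain_simulation(self):
        traj = predict_scenario(self.spec, self.params, 0.0, 30.0, 1.0, 2.0, horizon=6.0)
        from bufferguts import default_grid, simulate

        contact = ExposureProfile(1, "ug a.i./bee", ())
        oral = ExposureProfile(2, "mg a.i./kg food", ((1.0, 3.0, 30.0),))
        grid = default_grid([contact, oral], horizon=6.0)
        ref = simulate(self.spec, self.params, [contact, oral], grid)
        assert np.allclose(traj.survival_at(ref.times), ref.S, atol=1e-10)

    def test_final_survival_invariant_to_oral_start_when_pulses_resolve(self):
        # with hb = 0 and SD, the hazard picked up from each exposure episode
        # is additive as long as the damage excursions do not overlap, so the
        # final survival does not depend on when the oral window starts
        s1 = predict_scenario(self.spec, self.params, 0.15, 40.0, 3.0, 1.0, horizon=25.0)
        s2 = predict_scenario(self.spec, self.params, 0.15, 40.0, 8.0, 1.0, horizon=30.0)
        assert abs(s1.S[-1] - s2.S[-1]) < 1e-6

    def test_window_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            predict_scenario(self.spec, self.params, 0.1, 10.0, 4.0, 2.0, horizon=5.0)
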