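"""Initial-condition generation and integrator behaviour: determinism,
closed-form limits, conservation laws, and tolerance control."""

import numpy as np
import pytest

from qsflock.dynamics import ModelParams, PopulationState
from qsflock.kernels import ActivationParams, UptakeTimeParams
from qsflock.metrics import momentum_drift
from qsflock.simulate import (
    InitSpec,
    SimulationConfig,
    init_population,
    integrate,
    run_model,
)


class TestInitPopulation:
    def test_same_seed_identical(self):
        spec = InitSpec()
        assert init_population(spec, 50, seed=123) == init_population(spec, 50, seed=123)

    def test_ranges_respected(self):
        spec = InitSpec(v_range=((0.0, 20.0), (0.0, 30.0)))
        state = init_population(spec, 100, seed=1)
        assert np.all((state.v[:, 0] >= 0) & (state.v[:, 0] <= 20))
        assert np.all((state.v[:, 1] >= 0) & (state.v[:, 1] <= 30))
        assert np.all(state.p == 0) and np.all(state.A == 0)

    def test_point_box_degenerates(self):
        spec = InitSpec(x_range=((2.0, 2.0), (3.0, 3.0)))
        state = init_population(spec, 10, seed=0)
        np.testing.assert_array_equal(state.x, np.tile([2.0, 3.0], (10, 1)))

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            init_population(InitSpec(), 0, seed=0)

    def test_unordered_box_rejected(self):
        with pytest.raises(ValueError):
            InitSpec(x_range=((5.0, 1.0), (0.0, 1.0)))


def single_cell_state(v=(0.0, 0.0), p=0.0, A=0.0):
    return PopulationState(x=np.zeros((1, 2)), v=np.array([v], float), p=[p], A=[A])


def config_1(t_final, n_samples=2, **kw):
    return SimulationConfig(N=1, t_final=t_final, n_samples=n_samples, **kw)


class TestClosedForms:
    def test_velocity_relaxation(self):
        """N=1, no flocking: v(t) = v0 e_s (1 - exp(-F0 t))."""
        params = ModelParams(lambda1=0.0, lambda2=0.0, lambda3=0.0, F0=1.0)
        traj = integrate("uncoupled", params, single_cell_state(), config_1(3.0))
        expected = params.v0 * params.e_s * (1 - np.exp(-3.0))
        np.testing.assert_allclose(traj.final.v[0], expected, rtol=1e-6)

    def test_velocity_relaxation_general_start(self):
        """v(t) = v0 e_s + (v(0) - v0 e_s) exp(-F0 t)."""
        params = ModelParams(lambda1=0.0, lambda2=0.0, lambda3=0.0, F0=0.7)
        v0vec = params.v0 * params.e_s
        start = np.array([4.0, -2.0])
        traj = integrate("uncoupled", params, single_cell_state(v=start), config_1(2.5))
        expected = v0vec + (start - v0vec) * np.exp(-0.7 * 2.5)
        np.testing.assert_allclose(traj.final.v[0], expected, rtol=1e-6)

    def test_autoinducer_steady_state(self):
        """Fixed uptake: A -> lambda3 r / (ku + kd) for t >> 1/(ku+kd)."""
        up = UptakeTimeParams(k_min=0.4, k_max=0.4, rate=1.0, midpoint=0.0)
        params = ModelParams(
            lambda1=0.0, lambda2=0.0, lambda3=2.0, r=0.3, kd=0.1,
            uptake_mode="logistic_time", uptake_time=up,
        )
        traj = integrate("uncoupled", params, single_cell_state(), config_1(60.0))
        assert traj.final.A[0] == pytest.approx(2.0 * 0.3 / 0.5, rel=1e-6)

    def test_time_logistic_uptake_converges_autoinducer(self):
        """With the uptake ramping to k_max, A approaches lambda3 r/(k_max + kd)."""
        up = UptakeTimeParams(k_min=0.1, k_max=0.8, rate=2.0, midpoint=2.0)
        params = ModelParams(
            lambda1=0.0, lambda2=0.0, lambda3=1.0, r=0.5, kd=0.2,
            uptake_mode="logistic_time", uptake_time=up,
        )
        traj = integrate("uncoupled", params, single_cell_state(), config_1(100.0))
        assert traj.final.A[0] == pytest.approx(0.5 / 1.0, rel=1e-4)

    def test_protein_relaxation_frozen_activation(self):
        """With Psi_A frozen at psi: p(t) = p_inf + (p0 - p_inf) exp(-L0 psi t)."""
        # threshold far below zero freezes the logistic at exactly 1
        psiA = ActivationParams(steepness=100.0, threshold=-1e7, input_scale=1.0, exponent=1.0)
        params = ModelParams(lambda1=0.0, lambda2=0.0, lambda3=0.0, L0=0.8,
                             p_inf=1.5, psiA=psiA)
        traj = integrate("uncoupled", params, single_cell_state(p=0.2), config_1(4.0))
        expected = 1.5 + (0.2 - 1.5) * np.exp(-0.8 * 4.0)
        assert traj.final.p[0] == pytest.approx(expected, rel=1e-6)


def small_population(seed=0, n=12):
    spec = InitSpec(x_range=((0.0, 6.0), (0.0, 6.0)), v_range=((-2.0, 2.0), (-2.0, 2.0)))
    return init_population(spec, n, seed=seed)


class TestConservation:
    def test_total_velocity_conserved_without_source(self):
        params = ModelParams(F0=0.0, lambda1=3.0)
        config = SimulationConfig(N=12, t_final=5.0, n_samples=20)
        traj = integrate("uncoupled", params, small_population(), config)
        assert momentum_drift(traj) <= 1e-6

    def test_total_protein_conserved_without_source(self):
        params = ModelParams(L0=0.0, lambda2=2.0)
        state = small_population()
        state.p = np.linspace(0.0, 2.0, 12)
        config = SimulationConfig(N=12, t_final=5.0, n_samples=20)
        traj = integrate("uncoupled", params, state, config)
        totals = np.array([s.p.sum() for s in traj.states])
        assert np.max(np.abs(totals - totals[0])) <= 1e-6

    def test_nonnegativity_preserved(self):
        params = ModelParams()
        config = SimulationConfig(N=12, t_final=10.0, n_samples=30)
        traj = integrate("uncoupled", params, small_population(), config)
        assert all(np.all(s.p >= 0) and np.all(s.A >= 0) for s in traj.states)


class TestIntegrate:
    def test_reduction_coupled_equals_uncoupled(self):
        """Coupled run with an unreachable Psi_p threshold retraces the uncoupled run."""
        params = ModelParams().with_(
            psiP=ActivationParams(steepness=100.0, threshold=1e8, input_scale=1.0, exponent=1.0)
        )
        state = small_population()
        config = SimulationConfig(N=12, t_final=5.0, n_samples=10)
        a = integrate("uncoupled", params, state, config)
        b = integrate("coupled", params, state, config)
        for sa, sb in zip(a.states, b.states):
            np.testing.assert_allclose(sa.v, sb.v, atol=1e-8)
            np.testing.assert_allclose(sa.x, sb.x, atol=1e-8)

    def test_two_samples_gives_endpoints(self):
        params = ModelParams()
        config = SimulationConfig(N=5, t_final=2.0, n_samples=2)
        traj = run_model("uncoupled", params, config)
        np.testing.assert_array_equal(traj.times, [0.0, 2.0])
        assert len(traj.states) == 2

    def test_sample_grid_does_not_change_final_state(self):
        params = ModelParams()
        state = small_population()
        t2 = integrate("uncoupled", params, state,
                       SimulationConfig(N=12, t_final=4.0, n_samples=2))
        t50 = integrate("uncoupled", params, state,
                        SimulationConfig(N=12, t_final=4.0, n_samples=50))
        np.testing.assert_allclose(t2.final.v, t50.final.v, atol=1e-8)
        np.testing.assert_allclose(t2.final.x, t50.final.x, atol=1e-8)

    def test_halved_tolerances_barely_move_final_state(self):
        params = ModelParams()
        state = small_population()
        base = integrate("uncoupled", params, state,
                         SimulationConfig(N=12, t_final=4.0, n_samples=2))
        tight = integrate("uncoupled", params, state,
                          SimulationConfig(N=12, t_final=4.0, n_samples=2,
                                           rtol=5e-10, atol=5e-10))
        diff = np.linalg.norm(base.final.v - tight.final.v)
        assert diff < 1e-7

    def test_determinism_same_seed(self):
        params = ModelParams()
        config = SimulationConfig(N=8, t_final=2.0, n_samples=5, seed=42)
        a = run_model("uncoupled", params, config)
        b = run_model("uncoupled", params, config)
        for sa, sb in zip(a.states, b.states):
            assert sa == sb

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            integrate("hybrid", ModelParams(), small_population(),
                      SimulationConfig(N=12, t_final=1.0, n_samples=2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(N=10, t_final=1.0, n_samples=1)
        with pytest.raises(ValueError):
            SimulationConfig(N=10, t_final=1.0, rtol=0.0)
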