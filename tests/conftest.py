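"""Shared fixtures: random states, parameter sets, and the naive scalar
oracle for the vectorised right-hand sides."""

import numpy as np
import pytest

from qsflock.dynamics import ModelParams, PopulationState, StateDerivative
from qsflock.kernels import (
    ActivationParams,
    KernelParams,
    UptakeDistanceParams,
    UptakeKernelParams,
    UptakeTimeParams,
    activation,
    pair_weight,
    uptake_from_distance_sum,
    uptake_from_kernel_density,
    uptake_logistic_in_time,
)


def random_state(rng: np.random.Generator, n: int) -> PopulationState:
    return PopulationState(
        x=rng.uniform(-5, 5, (n, 2)),
        v=rng.uniform(-3, 3, (n, 2)),
        p=rng.uniform(0, 2, n),
        A=rng.uniform(0, 2, n),
    )


def random_params(rng: np.random.Generator, uptake_mode: str = "distance_sum") -> ModelParams:
    return ModelParams(
        lambda1=rng.uniform(0, 5),
        lambda2=rng.uniform(0, 2),
        lambda3=rng.uniform(0, 2),
        kernel1=KernelParams(beta=rng.uniform(0, 1.5)),
        kernel2=KernelParams(beta=rng.uniform(0, 1.5)),
        kernel3=KernelParams(beta=rng.uniform(0, 1.5)),
        F0=rng.uniform(0, 2),
        v0=rng.uniform(0, 3),
        v_inf=rng.uniform(3, 6),
        L0=rng.uniform(0, 2),
        p_inf=rng.uniform(0.5, 2),
        psiA=ActivationParams(
            steepness=rng.uniform(1, 20),
            threshold=rng.uniform(0, 1),
            input_scale=rng.uniform(0.5, 2),
            exponent=rng.uniform(0.5, 3),
        ),
        psiP=ActivationParams(
            steepness=rng.uniform(1, 20),
            threshold=rng.uniform(0, 1),
            input_scale=rng.uniform(0.5, 2),
            exponent=rng.uniform(0.5, 3),
        ),
        r=rng.uniform(0, 1),
        kd=rng.uniform(0, 1),
        uptake_mode=uptake_mode,
        uptake_distance=UptakeDistanceParams(
            amp=rng.uniform(0, 2),
            floor=rng.uniform(0, 0.5),
            gain=rng.uniform(0.5, 5),
            center=rng.uniform(0, 5),
            width=rng.uniform(1, 30),
            density_scale=rng.uniform(1e-4, 1e-2),
            beta_u=rng.uniform(0, 1.5),
        ),
        uptake_kernel=UptakeKernelParams(
            amp=rng.uniform(0, 2),
            floor=rng.uniform(0, 0.5),
            gain=rng.uniform(0.5, 5),
            center=rng.uniform(0, 5),
            width=rng.uniform(1, 30),
            density_scale=rng.uniform(0.5, 5),
        ),
        uptake_time=UptakeTimeParams(
            k_min=rng.uniform(0, 0.5),
            k_max=rng.uniform(0.5, 2),
            rate=rng.uniform(0.2, 3),
            midpoint=rng.uniform(0, 5),
        ),
    )


def naive_rhs(state: PopulationState, params: ModelParams, t: float, coupled: bool):
    """Scalar double-loop re-implementation of the model equations."""
    n = state.n
    dx = np.zeros((n, 2))
    dv = np.zeros((n, 2))
    dp = np.zeros(n)
    dA = np.zeros(n)
    for i in range(n):
        dx[i] = state.v[i]
        flock_v = np.zeros(2)
        flock_p = 0.0
        ksum3 = 0.0
        for j in range(n):
            flock_v += pair_weight(state.x[i], state.x[j], params.kernel1) * (
                state.v[j] - state.v[i]
            )
            flock_p += pair_weight(state.x[i], state.x[j], params.kernel2) * (
                state.p[j] - state.p[i]
            )
            ksum3 += pair_weight(state.x[i], state.x[j], params.kernel3)
        if coupled:
            psi = activation(state.p[i], params.psiP)
            target = (params.v0 + (params.v_inf - params.v0) * psi) * params.e_s
        else:
            target = params.v0 * params.e_s
        dv[i] = (params.lambda1 / n) * flock_v + params.F0 * (target - state.v[i])
        dp[i] = (params.lambda2 / n) * flock_p + params.L0 * (
            params.p_inf - state.p[i]
        ) * activation(state.A[i], params.psiA)
        if params.uptake_mode == "distance_sum":
            ku = uptake_from_distance_sum(state.x, i, params.uptake_distance)
        elif params.uptake_mode == "kernel_density":
            ku = uptake_from_kernel_density(state.x, i, params.kernel3, params.uptake_kernel)
        else:
            ku = float(uptake_logistic_in_time(t, params.uptake_time))
        synth = params.lambda3 * ksum3 * params.r
        if params.normalize_synthesis:
            synth /= n
        dA[i] = synth - (ku + params.kd) * state.A[i]
    return StateDerivative(x=dx, v=dv, p=dp, A=dA)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
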