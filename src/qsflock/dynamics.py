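"""State containers and right-hand sides of the 4N-dimensional ODE systems.

Each of N cells carries a 2-D position ``x_i``, a 2-D velocity ``v_i``, a
scalar quorum-sensing protein level ``p_i`` (AU) and a scalar local
autoinducer concentration ``A_i`` (AU).  Two model variants share the
position, protein and autoinducer equations:

    dx_i/dt = v_i
    dp_i/dt = (lambda2/N) sum_j k2(x_i,x_j)(p_j - p_i) + L0 (p_inf - p_i) Psi_A(A_i)
    dA_i/dt = lambda3 sum_j k3(x_i,x_j) r - ku(x_i, t) A_i - kd A_i

and differ in the velocity source term:

    uncoupled: dv_i/dt = (lambda1/N) sum_j k1(x_i,x_j)(v_j - v_i)
                          + F0 (v0 e_s - v_i)
    coupled:   dv_i/dt = (lambda1/N) sum_j k1(x_i,x_j)(v_j - v_i)
                          + F0 [v0 e_s + (v_inf - v0) e_s Psi_p(p_i) - v_i]

In the coupled variant cells whose protein passes the Psi_p switch chemotax
at the elevated speed ``v_inf`` instead of the base speed ``v0`` — this is
the feedback that produces emergent subgroup splitting.

Note the autoinducer synthesis sum carries no 1/N normalisation, unlike the
velocity and protein flocking terms; ``normalize_synthesis`` restores it for
sensitivity studies.  All sums include the self term j = i (the kernel
self-weight is 1; the flocking differences vanish at j = i, and the
synthesis/density terms gain a well-defined single-cell floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kernels import (
    ActivationParams,
    KernelParams,
    UptakeDistanceParams,
    UptakeKernelParams,
    UptakeTimeParams,
    activation,
    pairwise_weights,
    uptake_logistic_in_time,
)

__all__ = [
    "PopulationState",
    "StateDerivative",
    "ModelParams",
    "uncoupled_rhs",
    "coupled_rhs",
    "pack",
    "unpack",
    "uptake_rates",
]

UPTAKE_MODES = ("distance_sum", "kernel_density", "logistic_time")


def _as_block(name: str, value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class PopulationState:
    """Per-cell state (x_i, v_i, p_i, A_i) for N cells at one instant."""

    x: np.ndarray  # (N, 2) positions
    v: np.ndarray  # (N, 2) velocities
    p: np.ndarray  # (N,) protein levels, AU
    A: np.ndarray  # (N,) autoinducer concentrations, AU

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError(f"x must be (N, 2), got shape {np.shape(self.x)}")
        n = x.shape[0]
        self.x = _as_block("x", x, (n, 2))
        self.v = _as_block("v", self.v, (n, 2))
        self.p = _as_block("p", np.asarray(self.p, float).reshape(-1), (n,))
        self.A = _as_block("A", np.asarray(self.A, float).reshape(-1), (n,))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(self.x.copy(), self.v.copy(), self.p.copy(), self.A.copy())

    def __eq__(self, other) -> bool:  # exact, bitwise-level comparison
        if not isinstance(other, PopulationState):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.v, other.v)
            and np.array_equal(self.p, other.p)
            and np.array_equal(self.A, other.A)
        )


@dataclass
class StateDerivative:
    """Per-cell time derivatives, block-for-block with PopulationState."""

    x: np.ndarray
    v: np.ndarray
    p: np.ndarray
    A: np.ndarray


def _unit(vec) -> np.ndarray:
    arr = np.asarray(vec, dtype=float).reshape(2)
    norm = float(np.linalg.norm(arr))
    if abs(norm - 1.0) > 1e-12:
        raise ValueError(f"e_s must be a unit vector, |e_s| = {norm}")
    return arr


@dataclass
class ModelParams:
    """All model constants for both variants.

    Coupling strengths ``lambda1..3`` scale the flocking (population
    interaction) terms; ``F0`` and ``L0`` scale the chemotactic and
    expression source terms; ``v0``/``v_inf`` are the base and induced
    chemotaxis speeds along the attractant direction ``e_s``; ``r`` and
    ``kd`` are the autoinducer synthesis and degradation rates.  ``psiP``
    and ``v_inf`` only enter the coupled variant.
    """

    lambda1: float = 5.0
    lambda2: float = 0.0
    lambda3: float = 1.0
    kernel1: KernelParams = field(default_factory=KernelParams)
    kernel2: KernelParams = field(default_factory=KernelParams)
    kernel3: KernelParams = field(default_factory=KernelParams)
    F0: float = 1.0
    v0: float = 10.0
    v_inf: float = 10.0
    e_s: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]) / np.sqrt(2.0))
    L0: float = 1.0
    p_inf: float = 1.0
    psiA: ActivationParams = field(default_factory=ActivationParams)
    psiP: ActivationParams = field(default_factory=ActivationParams)
    r: float = 1.0
    kd: float = 0.1
    uptake_mode: str = "distance_sum"
    uptake_distance: UptakeDistanceParams = field(default_factory=UptakeDistanceParams)
    uptake_kernel: UptakeKernelParams = field(default_factory=UptakeKernelParams)
    uptake_time: UptakeTimeParams = field(default_factory=UptakeTimeParams)
    normalize_synthesis: bool = False

    def __post_init__(self) -> None:
        self.e_s = _unit(self.e_s)
        for name in ("lambda1", "lambda2", "lambda3", "F0", "v0", "v_inf", "L0", "p_inf", "r", "kd"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        if self.uptake_mode not in UPTAKE_MODES:
            raise ValueError(
                f"uptake_mode must be one of {UPTAKE_MODES}, got {self.uptake_mode!r}"
            )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def uptake_rates(state: PopulationState, params: ModelParams, t: float) -> np.ndarray:
    """Per-cell uptake rate ku for the configured uptake mode (vectorised)."""
    n = state.n
    if params.uptake_mode == "logistic_time":
        return np.full(n, float(uptake_logistic_in_time(t, params.uptake_time)))
    if params.uptake_mode == "distance_sum":
        up = params.uptake_distance
        diff = state.x[:, None, :] - state.x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        s = up.density_scale * np.sum(d2**up.beta_u, axis=1)
        return up.amp * np.exp(-((up.gain * s - up.center) ** 2) / (2.0 * up.width)) + up.floor
    up = params.uptake_kernel
    ksum = np.sum(pairwise_weights(state.x, params.kernel3), axis=1)
    density = up.density_scale * ksum if up.literal_formula else up.density_scale / ksum
    return up.amp * np.exp(-((up.gain * density - up.center) ** 2) / (2.0 * up.width)) + up.floor


def _shared_rhs(state: PopulationState, params: ModelParams, t: float):
    """Flocking terms and the p/A balances common to both variants."""
    n = state.n
    w1 = pairwise_weights(state.x, params.kernel1)
    w2 = pairwise_weights(state.x, params.kernel2)
    w3 = pairwise_weights(state.x, params.kernel3)

    # (lambda/N) sum_j w_ij (y_j - y_i) = (lambda/N) (W y - (W 1) y)
    row1 = w1.sum(axis=1)
    dv_flock = (params.lambda1 / n) * (w1 @ state.v - row1[:, None] * state.v)

    row2 = w2.sum(axis=1)
    dp_flock = (params.lambda2 / n) * (w2 @ state.p - row2 * state.p)
    dp = dp_flock + params.L0 * (params.p_inf - state.p) * activation(state.A, params.psiA)

    synth = params.lambda3 * w3.sum(axis=1) * params.r
    if params.normalize_synthesis:
        synth = synth / n
    ku = uptake_rates(state, params, t)
    dA = synth - (ku + params.kd) * state.A
    return dv_flock, dp, dA


def uncoupled_rhs(state: PopulationState, params: ModelParams, t: float = 0.0) -> StateDerivative:
    """Time derivative of the uncoupled model (expression does not feed back on motion)."""
    dv_flock, dp, dA = _shared_rhs(state, params, t)
    dv = dv_flock + params.F0 * (params.v0 * params.e_s[None, :] - state.v)
    return StateDerivative(x=state.v.copy(), v=dv, p=dp, A=dA)


def coupled_rhs(state: PopulationState, params: ModelParams, t: float = 0.0) -> StateDerivative:
    """Time derivative of the coupled model (protein level modulates chemotaxis speed)."""
    dv_flock, dp, dA = _shared_rhs(state, params, t)
    psi_p = activation(state.p, params.psiP)
    target = (params.v0 + (params.v_inf - params.v0) * psi_p)[:, None] * params.e_s[None, :]
    dv = dv_flock + params.F0 * (target - state.v)
    return StateDerivative(x=state.v.copy(), v=dv, p=dp, A=dA)


def pack(state: PopulationState) -> np.ndarray:
    """Flatten a state into a length-6N vector with block order (x, v, p, A)."""
    return np.concatenate([state.x.ravel(), state.v.ravel(), state.p, state.A])


def unpack(flat: np.ndarray, n: int) -> PopulationState:
    """Inverse of :func:`pack`; raises on a length mismatch."""
    flat = np.asarray(flat, dtype=float)
    expected = 6 * n
    if flat.shape != (expected,):
        raise ValueError(f"flat vector must have length {expected} for N={n}, got {flat.shape}")
    x = flat[: 2 * n].reshape(n, 2)
    v = flat[2 * n : 4 * n].reshape(n, 2)
    p = flat[4 * n : 5 * n]
    A = flat[5 * n :]
    return PopulationState(x=x, v=v, p=p, A=A)


def pack_derivative(deriv: StateDerivative) -> np.ndarray:
    return np.concatenate([deriv.x.ravel(), deriv.v.ravel(), deriv.p, deriv.A])
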