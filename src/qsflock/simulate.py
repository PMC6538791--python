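"""Seeded initial populations and adaptive ODE integration.

Initial positions and velocities are drawn i.i.d. uniform from configurable
boxes (protein and autoinducer start at configurable constants, zero by
default so that quorum-sensing expression emerges from the dynamics), using
numpy's PCG64 generator so a seed fully determines a run.  Integration uses
an adaptive embedded Runge-Kutta 4(5) method (scipy's RK45) with tight
default tolerances (rtol = atol = 1e-9) and samples the solution on a
uniform time grid via dense output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import (
    ModelParams,
    PopulationState,
    coupled_rhs,
    pack,
    pack_derivative,
    uncoupled_rhs,
    unpack,
)

__all__ = [
    "InitSpec",
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "init_population",
    "integrate",
    "run_model",
]

VARIANTS = ("uncoupled", "coupled")


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails (e.g. step-size underflow)."""


def _box(name: str, box) -> tuple[tuple[float, float], tuple[float, float]]:
    arr = np.asarray(box, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"{name} must be ((lo, hi), (lo, hi)), got {box!r}")
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValueError(f"{name} bounds must satisfy lo <= hi, got {box!r}")
    return ((arr[0, 0], arr[0, 1]), (arr[1, 0], arr[1, 1]))


@dataclass(frozen=True)
class InitSpec:
    """Uniform-box initial-condition specification."""

    x_range: tuple = ((0.0, 10.0), (0.0, 10.0))
    v_range: tuple = ((0.0, 20.0), (0.0, 30.0))
    p0: float = 0.0
    A0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_range", _box("x_range", self.x_range))
        object.__setattr__(self, "v_range", _box("v_range", self.v_range))
        if self.p0 < 0 or self.A0 < 0:
            raise ValueError("initial p0 and A0 must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    N: int = 100
    t_final: float = 15.0
    n_samples: int = 50
    rtol: float = 1e-9
    atol: float = 1e-9
    seed: int = 0
    init: InitSpec = field(default_factory=InitSpec)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.t_final <= 0:
            raise ValueError(f"t_final must be > 0, got {self.t_final}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be > 0")


@dataclass
class Trajectory:
    """Sampled solution of one run plus everything needed to reproduce it."""

    times: np.ndarray
    states: list  # list[PopulationState], one per sample time
    config: Optional[SimulationConfig] = None
    params: Optional[ModelParams] = None
    variant: str = "uncoupled"
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        ns = {s.n for s in self.states}
        if len(ns) > 1:
            raise ValueError("all states must share the same N")

    @property
    def n_cells(self) -> int:
        return self.states[0].n

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def block(self, name: str) -> np.ndarray:
        """Stack one state block over time: (n_times, N, 2) for x/v, (n_times, N) for p/A."""
        return np.stack([getattr(s, name) for s in self.states])


def init_population(spec: InitSpec, N: int, seed: int) -> PopulationState:
    """Draw a uniform-random initial population; identical seed, identical state."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    (xlo, xhi), (ylo, yhi) = spec.x_range
    x = np.column_stack([rng.uniform(xlo, xhi, N), rng.uniform(ylo, yhi, N)])
    (vxlo, vxhi), (vylo, vyhi) = spec.v_range
    v = np.column_stack([rng.uniform(vxlo, vxhi, N), rng.uniform(vylo, vyhi, N)])
    return PopulationState(x=x, v=v, p=np.full(N, spec.p0), A=np.full(N, spec.A0))


def integrate(
    variant: str,
    params: ModelParams,
    state0: PopulationState,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate one population with adaptive RK45 and sample a uniform grid."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    rhs = uncoupled_rhs if variant == "uncoupled" else coupled_rhs
    n = state0.n

    def fun(t, y):
        return pack_derivative(rhs(unpack(y, n), params, t))

    t_eval = np.linspace(0.0, config.t_final, config.n_samples)
    sol = solve_ivp(
        fun,
        (0.0, config.t_final),
        pack(state0),
        method="RK45",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}"
        )
    states = [unpack(sol.y[:, k], n) for k in range(sol.y.shape[1])]
    stats = {"nfev": int(sol.nfev), "n_samples": int(len(sol.t)), "status": int(sol.status)}
    return Trajectory(
        times=sol.t, states=states, config=config, params=params, variant=variant, stats=stats
    )


def run_model(
    variant: str,
    params: ModelParams,
    config: SimulationConfig,
    state0: Optional[PopulationState] = None,
) -> Trajectory:
    """Single entry point: initialise (unless warm-started) and integrate."""
    if state0 is None:
        state0 = init_population(config.init, config.N, config.seed)
    return integrate(variant, params, state0, config)
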