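"""Scripted in-silico scenarios with machine-checkable reports.

Five experiments exercise the model's qualitative regimes:

* velocity-consensus of a randomised population (uncoupled model),
* bimodal quorum-sensing protein expression driven by the shifted-Gaussian
  uptake (uncoupled),
* reversal of the density-expression association as the scope-of-influence
  exponent beta increases (uncoupled sweep),
* emergent splitting into a fast high-expression subgroup and a slow
  low-expression subgroup (coupled model, equal switch exponents),
* a transwell-style recruitment run (coupled model, motility switch more
  sensitive than the expression switch) counting membrane crossings and the
  GFP-positive fraction over time.

Only a few constants are dictated by the scenarios themselves (the
consensus run's lambda1 = 5, beta = 0.2, N = 100 and velocity ranges; the
expression runs' Gaussian-uptake constants a = 4, b = 4, c = 27.81 with
beta = 0.62 and density scale 1/2000; the 0.7 AU GFP threshold).  Every
other constant in the "fig-defaults" fixtures below was chosen once, by
manual tuning, so that each scenario sits inside its intended qualitative
regime; all are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import ModelParams
from .kernels import (
    ActivationParams,
    KernelParams,
    UptakeDistanceParams,
    UptakeKernelParams,
)
from .metrics import (
    FlockingDiagnostics,
    ModeReport,
    SubgroupReport,
    count_protein_modes,
    density_expression_correlation,
    detect_velocity_subgroups,
    flocking_check,
)
from .simulate import InitSpec, SimulationConfig, Trajectory, run_model

__all__ = [
    "TranswellConfig",
    "TranswellResult",
    "BetaSweepResult",
    "convergence_defaults",
    "expression_defaults",
    "subgroup_defaults",
    "transwell_defaults",
    "run_convergence_experiment",
    "run_bimodality_experiment",
    "run_beta_sweep",
    "run_subgroup_experiment",
    "run_transwell",
]

E_S = np.array([1.0, 1.0]) / np.sqrt(2.0)


# ---------------------------------------------------------------------------
# fig-defaults fixtures
# ---------------------------------------------------------------------------

def convergence_defaults() -> tuple[ModelParams, SimulationConfig]:
    """Velocity-consensus fixture: N=100, lambda1=5, beta=0.2, wide random velocities."""
    kernel = KernelParams(beta=0.2)
    params = ModelParams(
        lambda1=5.0,
        lambda2=0.5,
        lambda3=1.0,
        kernel1=kernel,
        kernel2=kernel,
        kernel3=kernel,
        F0=1.0,
        v0=10.0,
        e_s=E_S,
        L0=0.5,
        p_inf=1.0,
        psiA=ActivationParams(steepness=10.0, threshold=1.0, input_scale=1.0, exponent=1.0),
        r=0.1,
        kd=0.1,
        uptake_mode="distance_sum",
        uptake_distance=UptakeDistanceParams(),
    )
    config = SimulationConfig(
        N=100,
        t_final=15.0,
        n_samples=60,
        init=InitSpec(
            x_range=((0.0, 10.0), (0.0, 10.0)),
            v_range=((0.0, 20.0), (0.0, 30.0)),
        ),
    )
    return params, config


def expression_defaults(beta: float = 0.62) -> tuple[ModelParams, SimulationConfig]:
    """Expression fixture (bimodality / beta sweep): shifted-Gaussian uptake.

    Uptake constants gain=4, center=4, width=27.81 and density scale 1/2000
    define the scenario; a single beta plays both kernel and uptake-exponent
    roles.
    """
    kernel = KernelParams(beta=beta)
    params = ModelParams(
        lambda1=1.0,
        lambda2=0.1,
        lambda3=1.0,
        kernel1=kernel,
        kernel2=kernel,
        kernel3=kernel,
        F0=1.0,
        v0=10.0,
        e_s=E_S,
        L0=0.5,
        p_inf=1.0,
        # sharp switch whose threshold sits inside the steady-state A spread,
        # so the Gaussian uptake bisects the population into expressers and
        # non-expressers
        psiA=ActivationParams(steepness=100.0, threshold=0.6, input_scale=1.0, exponent=1.0),
        r=0.1,
        kd=0.1,
        uptake_mode="distance_sum",
        uptake_distance=UptakeDistanceParams(
            amp=1.0,
            floor=0.1,
            gain=4.0,
            center=4.0,
            width=27.81,
            density_scale=1.0 / 2000.0,
            beta_u=beta,
        ),
    )
    config = SimulationConfig(
        N=100,
        t_final=40.0,
        n_samples=80,
        init=InitSpec(
            x_range=((0.0, 30.0), (0.0, 30.0)),
            v_range=((0.0, 5.0), (0.0, 5.0)),
        ),
    )
    return params, config


def subgroup_defaults() -> tuple[ModelParams, SimulationConfig]:
    """Coupled-model fixture with equal switch exponents (alpha1 = alpha2 = 1).

    Starts from an already-aligned marching population; the coupled feedback
    lets the high-expression fraction accelerate toward v_inf and split off.
    """
    params, config = expression_defaults(beta=0.62)
    # slower expression (L0) and a high motility threshold widen the window
    # in which the early-deciding expressers have split off while the
    # left-behind group has not yet accumulated enough protein to accelerate
    params = params.with_(
        v_inf=30.0,
        L0=0.2,
        psiP=ActivationParams(steepness=100.0, threshold=0.8, input_scale=1.0, exponent=1.0),
    )
    config = SimulationConfig(
        N=config.N,
        t_final=16.0,
        n_samples=65,
        init=InitSpec(
            x_range=((0.0, 30.0), (0.0, 30.0)),
            v_range=((6.9, 7.2), (6.9, 7.2)),  # tight jitter around v0 * e_s
        ),
    )
    return params, config


def transwell_defaults() -> tuple[ModelParams, SimulationConfig]:
    """Coupled-model fixture in the alpha1 < alpha2 regime with kernel-density uptake.

    The motility switch (Psi_p) is more sensitive — lower threshold, smaller
    exponent — than the expression switch (Psi_A), so cells migrate before
    they express.
    """
    kernel = KernelParams(beta=0.62)
    params = ModelParams(
        lambda1=1.0,
        lambda2=0.1,
        lambda3=1.0,
        kernel1=kernel,
        kernel2=kernel,
        kernel3=kernel,
        F0=1.0,
        v0=2.0,
        v_inf=6.0,
        e_s=E_S,
        L0=0.05,
        p_inf=1.0,
        # alpha1 < alpha2: the motility switch trips at a tiny protein level,
        # the expression switch needs substantial autoinducer and is skewed
        # (exponent 2), so migration precedes GFP accumulation
        psiP=ActivationParams(steepness=100.0, threshold=0.05, input_scale=1.0, exponent=1.0),
        psiA=ActivationParams(steepness=10.0, threshold=0.5, input_scale=1.0, exponent=2.0),
        r=0.1,
        kd=0.1,
        uptake_mode="kernel_density",
        uptake_kernel=UptakeKernelParams(
            amp=1.0, floor=0.1, gain=4.0, center=4.0, width=27.81, density_scale=1.0
        ),
    )
    config = SimulationConfig(
        N=100,
        t_final=48.0,
        n_samples=97,
        init=InitSpec(
            x_range=((0.0, 10.0), (0.0, 10.0)),
            v_range=((0.0, 2.0), (0.0, 2.0)),
        ),
    )
    return params, config


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_convergence_experiment(
    seed: int = 0,
    params: Optional[ModelParams] = None,
    config: Optional[SimulationConfig] = None,
) -> tuple[Trajectory, FlockingDiagnostics]:
    """Randomised 100-cell population converging to the consensus velocity v0*e_s."""
    default_params, default_config = convergence_defaults()
    params = params or default_params
    config = config or default_config
    config = SimulationConfig(
        N=config.N, t_final=config.t_final, n_samples=config.n_samples,
        rtol=config.rtol, atol=config.atol, seed=seed, init=config.init,
    )
    traj = run_model("uncoupled", params, config)
    return traj, flocking_check(traj)


def run_bimodality_experiment(
    seed: int = 0,
    sample_times: Optional[Sequence[float]] = None,
    params: Optional[ModelParams] = None,
    config: Optional[SimulationConfig] = None,
) -> tuple[Trajectory, list[ModeReport]]:
    """Protein-level mode reports at three (by default) increasing times."""
    default_params, default_config = expression_defaults()
    params = params or default_params
    config = config or default_config
    config = SimulationConfig(
        N=config.N, t_final=config.t_final, n_samples=config.n_samples,
        rtol=config.rtol, atol=config.atol, seed=seed, init=config.init,
    )
    if sample_times is None:
        sample_times = [0.25 * config.t_final, 0.5 * config.t_final, config.t_final]
    traj = run_model("uncoupled", params, config)
    reports = []
    for t in sample_times:
        idx = int(np.argmin(np.abs(traj.times - t)))
        reports.append(count_protein_modes(traj.states[idx].p))
    return traj, reports


@dataclass
class BetaSweepResult:
    betas: list
    correlations: list
    trajectories: Optional[list] = None

    def to_dict(self) -> dict:
        return {
            "betas": [float(b) for b in self.betas],
            "correlations": [float(c) for c in self.correlations],
        }


def run_beta_sweep(
    betas: Sequence[float] = (0.55, 0.6, 0.65, 0.7),
    seed: int = 0,
    keep_trajectories: bool = False,
) -> BetaSweepResult:
    """Density-expression rank correlation at the final time, one run per beta.

    All runs share the seed, hence the same initial population.
    """
    correlations, trajectories = [], []
    for beta in betas:
        params, config = expression_defaults(beta=beta)
        config = SimulationConfig(
            N=config.N, t_final=config.t_final, n_samples=config.n_samples,
            rtol=config.rtol, atol=config.atol, seed=seed, init=config.init,
        )
        traj = run_model("uncoupled", params, config)
        correlations.append(density_expression_correlation(traj.final, params.kernel3))
        if keep_trajectories:
            trajectories.append(traj)
    return BetaSweepResult(list(betas), correlations, trajectories or None)


def run_subgroup_experiment(
    seed: int = 0,
    sample_times: Optional[Sequence[float]] = None,
    variant: str = "coupled",
    params: Optional[ModelParams] = None,
    config: Optional[SimulationConfig] = None,
) -> tuple[Trajectory, list[SubgroupReport]]:
    """Speed-subgroup reports over time for the coupled model (or its uncoupled control)."""
    default_params, default_config = subgroup_defaults()
    params = params or default_params
    config = config or default_config
    config = SimulationConfig(
        N=config.N, t_final=config.t_final, n_samples=config.n_samples,
        rtol=config.rtol, atol=config.atol, seed=seed, init=config.init,
    )
    if sample_times is None:
        sample_times = np.linspace(0.0, config.t_final, 9)
    traj = run_model(variant, params, config)
    reports = []
    for t in sample_times:
        idx = int(np.argmin(np.abs(traj.times - t)))
        reports.append(detect_velocity_subgroups(traj.states[idx]))
    return traj, reports


@dataclass
class TranswellConfig:
    """Transwell-style recruitment scenario.

    The two-chamber apparatus is reduced to one dimension: a cell is "in the
    lower chamber" once its position projected on the chemoattractant
    direction e_s exceeds ``membrane_distance``.  Cells are counted, never
    removed.  A crossed cell is GFP-positive at a sample time when its
    instantaneous protein level exceeds ``gfp_threshold`` (0.7 AU).
    """

    membrane_distance: float = 60.0
    gfp_threshold: float = 0.7
    sample_times: Sequence[float] = (0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0)
    params: ModelParams = field(default_factory=lambda: transwell_defaults()[0])
    config: SimulationConfig = field(default_factory=lambda: transwell_defaults()[1])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_distance <= 0:
            raise ValueError(f"membrane_distance must be > 0, got {self.membrane_distance}")
        if not 0 < self.gfp_threshold < self.params.p_inf:
            raise ValueError(
                f"gfp_threshold must lie in (0, p_inf={self.params.p_inf}), "
                f"got {self.gfp_threshold}"
            )
        st = np.asarray(self.sample_times, dtype=float)
        if st.size < 2 or np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must be >= 2 strictly increasing times")


@dataclass
class TranswellResult:
    times: np.ndarray
    crossed_count: np.ndarray   # cumulative cells ever past the membrane
    gfp_fraction: np.ndarray    # fraction of crossed cells with p > threshold (NaN before first crossing)
    trajectory: Optional[Trajectory] = None

    def half_max_times(self) -> tuple[float, float]:
        """(first time crossings reach half their final value,
        first time the GFP fraction reaches half its final value)."""
        t_cross = _half_time(self.times, self.crossed_count.astype(float))
        gfp = np.where(np.isnan(self.gfp_fraction), 0.0, self.gfp_fraction)
        t_gfp = _half_time(self.times, gfp)
        return t_cross, t_gfp

    def to_dict(self) -> dict:
        return {
            "times": [float(t) for t in self.times],
            "crossed_count": [int(c) for c in self.crossed_count],
            "gfp_fraction": [None if np.isnan(g) else float(g) for g in self.gfp_fraction],
        }


def _half_time(times: np.ndarray, series: np.ndarray) -> float:
    final = series[-1]
    if final <= 0:
        return float("nan")
    idx = int(np.argmax(series >= 0.5 * final))
    return float(times[idx])


def tally_transwell(
    traj: Trajectory,
    e_s: np.ndarray,
    membrane_distance: float,
    gfp_threshold: float,
    sample_times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative crossing counts and GFP-positive fractions at sample times.

    A cell counts as crossed from the first sampled instant its projection on
    ``e_s`` exceeds ``membrane_distance`` (once crossed, always counted); the
    GFP fraction at a time is computed over the crossed cells from their
    *instantaneous* protein levels, strictly above ``gfp_threshold``.
    """
    proj = traj.block("x") @ np.asarray(e_s, float)             # (n_times, N)
    crossed = np.maximum.accumulate(proj > membrane_distance, axis=0)
    p = traj.block("p")
    counts, fractions = [], []
    for t in sample_times:
        idx = max(int(np.searchsorted(traj.times, t, side="right") - 1), 0)
        c = crossed[idx]
        counts.append(int(c.sum()))
        fractions.append(float(np.mean(p[idx][c] > gfp_threshold)) if c.any() else float("nan"))
    return np.array(counts), np.array(fractions)


def run_transwell(tw: Optional[TranswellConfig] = None) -> TranswellResult:
    """Simulate the coupled model and count membrane crossings / GFP fractions."""
    tw = tw or TranswellConfig()
    config = SimulationConfig(
        N=tw.config.N, t_final=tw.config.t_final, n_samples=tw.config.n_samples,
        rtol=tw.config.rtol, atol=tw.config.atol, seed=tw.seed, init=tw.config.init,
    )
    traj = run_model("coupled", tw.params, config)
    counts, fractions = tally_transwell(
        traj, tw.params.e_s, tw.membrane_distance, tw.gfp_threshold, tw.sample_times
    )
    if counts[-1] == 0:
        warnings.warn(
            f"no cell reached membrane_distance={tw.membrane_distance} "
            f"within t_final={config.t_final}",
            stacklevel=2,
        )
    return TranswellResult(
        times=np.asarray(tw.sample_times, dtype=float),
        crossed_count=counts,
        gfp_fraction=fractions,
        trajectory=traj,
    )
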