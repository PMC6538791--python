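"""Distance-decay weights, logistic activations, and autoinducer-uptake rates.

These are the scalar building blocks of the population-interaction model:

* ``pair_weight`` — the symmetric Cucker-Smale influence weight
  ``k(x_i, x_j) = 1 / (1 + |x_j - x_i|^2)^beta``.  The exponent ``beta`` is
  the "scope of influence": ``beta = 0`` weights every neighbour equally,
  larger ``beta`` makes influence increasingly local.
* ``activation`` — a generalised logistic switch used both for
  autoinducer-triggered expression (Psi_A) and for expression-coupled
  motility (Psi_p).
* three uptake-rate variants for the autoinducer balance: a shifted
  Gaussian in the summed pairwise distances (crowding reduces metabolic
  activity, so uptake peaks at intermediate density), the same Gaussian
  driven by a kernel-based density measure, and a logistic ramp in time.

All functions accept scalars or numpy arrays and are overflow-safe: the
logistic saturates to its 0/1 limits rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "ActivationParams",
    "UptakeDistanceParams",
    "UptakeKernelParams",
    "UptakeTimeParams",
    "pair_weight",
    "pairwise_weights",
    "activation",
    "uptake_from_distance_sum",
    "uptake_from_kernel_density",
    "uptake_logistic_in_time",
]


def _require_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


@dataclass(frozen=True)
class KernelParams:
    """Scope-of-influence exponent for the pairwise weight kernel."""

    beta: float = 0.2

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be a finite nonnegative real, got {self.beta}")


@dataclass(frozen=True)
class ActivationParams:
    """Generalised logistic switch 1 / (1 + exp(k(theta - s*u)))^alpha.

    ``steepness`` (k) sets how sharp the switch is, ``threshold`` (theta) where
    it turns on, ``input_scale`` (s) rescales the input, and ``exponent``
    (alpha) skews the transition — larger alpha demands a larger input for the
    same output, which is how the model encodes differing sensitivities of
    motility vs expression.
    """

    steepness: float = 10.0
    threshold: float = 0.5
    input_scale: float = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")
        if self.input_scale <= 0:
            raise ValueError(f"input_scale must be > 0, got {self.input_scale}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")
        _require_finite("threshold", self.threshold)


def _validate_gaussian(width: float, floor: float, amp: float) -> None:
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    if floor < 0:
        raise ValueError(f"floor must be >= 0, got {floor}")
    if amp < 0:
        raise ValueError(f"amp must be >= 0, got {amp}")


@dataclass(frozen=True)
class UptakeDistanceParams:
    """Shifted-Gaussian uptake driven by the summed pairwise distances.

    The density proxy for cell i is ``S = density_scale * sum_j |x_j - x_i|^(2*beta_u)``;
    uptake is ``amp * exp(-(gain*S - center)^2 / (2*width)) + floor``.  Uptake
    therefore rises with density up to a peak and falls off under overcrowding,
    never dropping below ``floor``.
    """

    amp: float = 1.0
    floor: float = 0.1
    gain: float = 4.0
    center: float = 4.0
    width: float = 27.81
    density_scale: float = 1.0 / 2000.0
    beta_u: float = 0.62

    def __post_init__(self) -> None:
        _validate_gaussian(self.width, self.floor, self.amp)
        if self.density_scale <= 0:
            raise ValueError(f"density_scale must be > 0, got {self.density_scale}")
        if self.beta_u < 0:
            raise ValueError(f"beta_u must be >= 0, got {self.beta_u}")


@dataclass(frozen=True)
class UptakeKernelParams:
    """Shifted-Gaussian uptake driven by a kernel-sum density measure.

    By default the density measure is the *inverse* of the kernel sum,
    ``D = density_scale / sum_j k3(x_i, x_j)`` (a crowded cell has a large
    kernel sum and hence a small D).  Setting ``literal_formula=True`` uses
    ``D = density_scale * sum_j k3`` instead.
    """

    amp: float = 1.0
    floor: float = 0.1
    gain: float = 4.0
    center: float = 4.0
    width: float = 27.81
    density_scale: float = 1.0
    literal_formula: bool = False

    def __post_init__(self) -> None:
        _validate_gaussian(self.width, self.floor, self.amp)
        if self.density_scale <= 0:
            raise ValueError(f"density_scale must be > 0, got {self.density_scale}")


@dataclass(frozen=True)
class UptakeTimeParams:
    """Logistic-in-time uptake ramp from k_min up to k_max."""

    k_min: float = 0.1
    k_max: float = 1.0
    rate: float = 1.0
    midpoint: float = 5.0

    def __post_init__(self) -> None:
        if self.k_min < 0:
            raise ValueError(f"k_min must be >= 0, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(f"k_max ({self.k_max}) must be >= k_min ({self.k_min})")
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        _require_finite("midpoint", self.midpoint)


def pair_weight(xi, xj, params: KernelParams):
    """Symmetric influence weight ``1 / (1 + |x_j - x_i|^2)^beta`` in (0, 1]."""
    xi = _require_finite("xi", xi)
    xj = _require_finite("xj", xj)
    d2 = np.sum((np.asarray(xj, float) - np.asarray(xi, float)) ** 2, axis=-1)
    return (1.0 + d2) ** (-params.beta)


def pairwise_weights(positions: np.ndarray, params: KernelParams) -> np.ndarray:
    """Full N x N weight matrix over a position array (self-weights are 1)."""
    positions = _require_finite("positions", positions)
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    return (1.0 + d2) ** (-params.beta)


def activation(value, params: ActivationParams):
    """Evaluate the logistic switch; saturates at 0/1 instead of overflowing.

    Computed as ``exp(-exponent * log(1 + exp(z)))`` with
    ``z = steepness * (threshold - input_scale * value)`` via ``logaddexp``,
    which is exact in both tails.
    """
    value = _require_finite("value", value)
    z = params.steepness * (params.threshold - params.input_scale * value)
    return np.exp(-params.exponent * np.logaddexp(0.0, z))


def _distance_sum(positions: np.ndarray, i: int, beta_u: float) -> float:
    diff = positions - positions[i]
    d2 = np.einsum("jk,jk->j", diff, diff)
    # numpy's 0**0 == 1 covers the beta_u = 0 limit (every term counts as 1)
    return float(np.sum(d2**beta_u))


def _shifted_gaussian(density: float, amp, floor, gain, center, width):
    return amp * np.exp(-((gain * density - center) ** 2) / (2.0 * width)) + floor


def uptake_from_distance_sum(
    positions: np.ndarray, i: int, params: UptakeDistanceParams
) -> float:
    """Uptake rate of cell ``i`` from the summed-pairwise-distance density proxy."""
    positions = np.atleast_2d(_require_finite("positions", positions))
    if not 0 <= i < positions.shape[0]:
        raise ValueError(f"cell index {i} out of range for N={positions.shape[0]}")
    s = params.density_scale * _distance_sum(positions, i, params.beta_u)
    return float(
        _shifted_gaussian(s, params.amp, params.floor, params.gain, params.center, params.width)
    )


def uptake_from_kernel_density(
    positions: np.ndarray,
    i: int,
    kernel: KernelParams,
    params: UptakeKernelParams,
) -> float:
    """Uptake rate of cell ``i`` from the kernel-sum density measure.

    The self-term k(x_i, x_i) = 1 guarantees the kernel sum is >= 1, so the
    inverse-density form never divides by zero.
    """
    positions = np.atleast_2d(_require_finite("positions", positions))
    if not 0 <= i < positions.shape[0]:
        raise ValueError(f"cell index {i} out of range for N={positions.shape[0]}")
    ksum = float(np.sum(pair_weight(positions[i], positions, kernel)))
    if params.literal_formula:
        density = params.density_scale * ksum
    else:
        density = params.density_scale / ksum
    return float(
        _shifted_gaussian(
            density, params.amp, params.floor, params.gain, params.center, params.width
        )
    )


def uptake_logistic_in_time(t, params: UptakeTimeParams):
    """Uptake rate ramping logistically from ``k_min`` (early) to ``k_max`` (late)."""
    t = _require_finite("t", t)
    z = -params.rate * (t - params.midpoint)
    return params.k_min + (params.k_max - params.k_min) * np.exp(-np.logaddexp(0.0, z))
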