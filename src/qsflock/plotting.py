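"""Optional static-figure helpers (matplotlib).

Not imported by the package root; import explicitly when needed.
"""

from __future__ import annotations

import numpy as np

from .metrics import FlockingDiagnostics
from .simulate import Trajectory


def plot_trajectories(traj: Trajectory, ax=None, cmap: str = "summer_r"):
    """Cell paths coloured by final protein level (low = green, high = yellow).

    Each cell's trail is drawn from t = 0; the final position is marked with
    a dot coloured by its protein level.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    x = traj.block("x")
    p_final = traj.final.p
    cm = plt.get_cmap(cmap)
    span = np.ptp(p_final) or 1.0
    colors = cm((p_final - p_final.min()) / span)
    for i in range(traj.n_cells):
        ax.plot(x[:, i, 0], x[:, i, 1], color=colors[i], lw=0.6, alpha=0.7)
    ax.scatter(x[-1, :, 0], x[-1, :, 1], c=colors, s=18, zorder=3)
    ax.set_xlabel("x (AU)")
    ax.set_ylabel("y (AU)")
    return ax


def plot_flocking(diag: FlockingDiagnostics, ax=None):
    """Velocity and position diameters over time on a log scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.semilogy(diag.times, np.maximum(diag.Dv, 1e-300), label="velocity diameter")
    ax.semilogy(diag.times, np.maximum(diag.Dx, 1e-300), label="position diameter")
    ax.set_xlabel("time (AU)")
    ax.set_ylabel("diameter (AU)")
    ax.legend()
    return ax
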