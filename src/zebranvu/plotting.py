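"""Quick-look figures: speed-classed trajectories and peak-annotated traces."""

from __future__ import annotations

import numpy as np

from .calcium import CalciumTrace, TransientSet
from .features import SpeedThresholds, classify_speed, instantaneous_speeds
from .io import Trajectory, WellGeometry

__all__ = ["plot_trajectory", "plot_trace_with_peaks"]

# tracker-style colours: high = red, low = green, inactive = black
CLASS_COLOURS = {"inactive": "black", "low": "green", "high": "red"}


def plot_trajectory(
    traj: Trajectory,
    well: WellGeometry,
    thresholds: SpeedThresholds = SpeedThresholds(),
    ax=None,
):
    """Draw the swim path coloured by speed class inside the well outline."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    classes = classify_speed(instantaneous_speeds(traj), thresholds)
    pts = traj.points
    for cls, colour in CLASS_COLOURS.items():
        sel = classes == cls
        segs = np.stack([pts[:-1][sel], pts[1:][sel]], axis=1)
        ax.add_collection(LineCollection(segs, colors=colour, linewidths=0.5, label=cls))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(well.centre[0] + well.radius * np.cos(theta),
            well.centre[1] + well.radius * np.sin(theta), color="grey", lw=1)
    nx, ny = well.divider_normal
    # divider line is perpendicular to its normal
    ax.plot([well.centre[0] - well.radius * -ny, well.centre[0] + well.radius * -ny],
            [well.centre[1] - well.radius * nx, well.centre[1] + well.radius * nx],
            color="grey", lw=1, ls="--")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_trace_with_peaks(trace: CalciumTrace, dff: np.ndarray, transients: TransientSet, ax=None):
    """ΔF/F₀ trace with arrowheads at the detected transient onsets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.t, dff, lw=0.8, color="tab:green")
    if len(transients.peak_times):
        idx = np.searchsorted(trace.t, transients.peak_times)
        idx = np.clip(idx, 0, len(dff) - 1)
        ax.plot(trace.t[idx], dff[idx] + 0.02, marker="v", ls="none", color="black",
                markersize=5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F₀")
    return ax
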