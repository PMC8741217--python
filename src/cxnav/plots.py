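"""Optional figure output: trajectory panels, time series, rose plots.

Everything here is presentation only; nothing downstream depends on it.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import metrics
from .fields import raster

__all__ = ["plot_trajectories", "plot_anemotaxis_timeseries", "plot_heading_rose", "plot_field"]


def plot_trajectories(ts, path, field_extent=None, grid=80):
    """All trajectories over a concentration raster (if the config has a field)."""
    cfg = ts.config
    fig, ax = plt.subplots(figsize=(6, 6))
    fields = cfg.make_fields()
    if fields:
        if field_extent is None:
            pad = 2.0
            xs = ts.frame["x"]
            ys = ts.frame["y"]
            field_extent = (xs.min() - pad, xs.max() + pad, ys.min() - pad, ys.max() + pad)
        x0, x1, y0, y1 = field_extent
        X, Y, C = raster(fields, (x0, x1), (y0, y1), grid)
        ax.pcolormesh(X, Y, C, cmap="Greys", shading="auto")
    for (_, _), traj in ts.frame.groupby(["run", "agent"]):
        ax.plot(traj["x"], traj["y"], lw=0.8)
        ax.plot(traj["x"].iloc[0], traj["y"].iloc[0], "g.", ms=5)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"{cfg.name} (seed {ts.seed})")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_anemotaxis_timeseries(ts, path):
    """Per-step upwind speed and |turn| for the first agent of each repeat."""
    cfg = ts.config
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for rep, d in ts.frame.groupby("run"):
        a0 = d[(d["agent"] == 0) & (d["mode"] != "END")]
        up = metrics.upwind_speed(a0, cfg.wind.w_theta, cfg.step_length)
        axes[0].plot(a0["t"], up, lw=0.8)
        axes[1].plot(a0["t"], a0["turn"].abs(), lw=0.8)
    if cfg.odour_window is not None:
        for ax in axes:
            ax.axvspan(
                cfg.odour_window[0] * cfg.steps,
                cfg.odour_window[1] * cfg.steps,
                color="m", alpha=0.15,
            )
    axes[0].set_ylabel("upwind speed")
    axes[1].set_ylabel("|turn| (rad/step)")
    axes[1].set_xlabel("step")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heading_rose(ts, path, at_step=None):
    """Rose plot of agent headings (final recorded step by default)."""
    df = ts.frame[ts.frame["mode"] != "END"]
    if at_step is None:
        headings = df.groupby(["run", "agent"]).tail(1)["heading"].to_numpy()
    else:
        headings = df[df["t"] == at_step]["heading"].to_numpy()
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    bins = np.linspace(-math.pi, math.pi, 25)
    counts, edges = np.histogram(headings, bins=bins)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", alpha=0.7)
    ax.set_title(f"headings ({ts.config.name})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_field(fields, extent, path, grid=150):
    """Concentration raster of one field (or a list, summed)."""
    x0, x1, y0, y1 = extent
    X, Y, C = raster(fields, (x0, x1), (y0, y1), grid)
    fig, ax = plt.subplots(figsize=(6, 5))
    pm = ax.pcolormesh(X, Y, C, cmap="viridis", shading="auto")
    fig.colorbar(pm, ax=ax, label="concentration (a.u.)")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
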