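"""Polar figures: decay petal plots, normative contours, rose histograms.

Figures are artifacts for inspection; tests assert the numeric layers
behind them, not pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; these are file-output plots

import matplotlib.pyplot as plt
import numpy as np

from .grid import AngularGrid
from .normative import NormativeCatalog
from .petals import DEFAULT_TAU, summarize_decay, trace_petals, widest_petal
from .profiles import GroupLabel

_TSNIT_TICKS = {0: "T", 90: "S", 180: "N", 270: "I"}


def _polar_axes():
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)  # counterclockwise TSNIT
    ax.set_xticks([np.deg2rad(a) for a in _TSNIT_TICKS])
    ax.set_xticklabels(_TSNIT_TICKS.values())
    return fig, ax


def plot_decay(decay: np.ndarray, path: str | Path, tau: float = DEFAULT_TAU) -> Path:
    """Petal plot of one eye's Angular Decay sequence.

    Threshold circle at radius tau in pale blue; sub-threshold decay in
    blue, petals in pink, the widest petal in red with a dashed radial
    line at its decay-weighted mean angle mu*.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.size == 0:
        raise ValueError("decay sequence is empty")
    grid = AngularGrid(decay.size)
    theta = np.deg2rad(grid.theta)
    fig, ax = _polar_axes()
    ax.plot(
        np.append(theta, theta[0]),
        np.full(decay.size + 1, tau),
        color="lightblue", lw=2,
    )
    below = np.where(decay <= tau, decay, np.nan)
    ax.plot(np.append(theta, theta[0]), np.append(below, below[0]), color="tab:blue", lw=1)

    petals = trace_petals(decay, tau)
    star = widest_petal(petals)
    for petal in petals:
        idx = petal.member_indices - 1
        color = "red" if star is not None and petal.start == star.start else "pink"
        ax.plot(theta[idx], decay[idx], color=color, lw=1.8)
    summary = summarize_decay(decay, tau, grid)
    if np.isfinite(summary.mu_star):
        ax.plot(
            [np.deg2rad(summary.mu_star)] * 2, [0, 1],
            linestyle="--", color="red", lw=1,
        )
    ax.set_ylim(0, 1)
    ax.set_title(
        f"tau={tau:g}  nu={summary.nu}  lambda*={summary.lambda_star:.4f}  "
        f"Lambda={summary.Lambda:.4f}", fontsize=9,
    )
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_contours(
    catalog: NormativeCatalog,
    group: GroupLabel,
    path: str | Path,
    probs=(0.05, 0.25, 0.5, 0.75),
) -> Path:
    """Concentric normative percentile contours for one stratum."""
    contours = catalog.quantile_contours(group, list(probs))
    grid = AngularGrid(catalog.n_points)
    theta = np.deg2rad(np.append(grid.theta, 360.0))
    fig, ax = _polar_axes()
    colors = ["red", "orange", "gold", "green", "teal", "purple"]
    for i, (name, row) in enumerate(contours.iterrows()):
        values = np.append(row.to_numpy(), row.to_numpy()[0])
        ax.plot(theta, values, color=colors[i % len(colors)], lw=1.2, label=name)
    ax.legend(loc="upper right", fontsize=7)
    ax.set_title(f"normative RNFL contours, {group}", fontsize=9)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_rose(angles_deg, path: str | Path, fit=None, bins: int = 36) -> Path:
    """Rose histogram of decay directions with optional mixture density."""
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("no finite angles to plot")
    fig, ax = _polar_axes()
    edges = np.linspace(0, 2 * np.pi, bins + 1)
    counts, _ = np.histogram(np.deg2rad(angles % 360.0), bins=edges)
    ax.bar(
        (edges[:-1] + edges[1:]) / 2, counts / counts.max(),
        width=np.diff(edges), color="salmon", alpha=0.7, edgecolor="darkred",
    )
    if fit is not None:
        from .mixture import vm_pdf

        xs = np.linspace(0, 360, 721)
        dens = np.zeros_like(xs)
        for mu, kappa, w in zip(fit.means_deg_, fit.kappas_, fit.weights_):
            dens += w * vm_pdf(xs, mu, kappa)
        ax.plot(np.deg2rad(xs), dens / dens.max(), color="black", lw=1.2)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
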