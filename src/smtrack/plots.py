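"""Static figure output for the standard post-processing products."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .colocalize import ColocalizedPair
from .diffusion import DiffusionResult, MSDCurve
from .intensity import IsingleEstimate, StoichiometryResult
from .track import Trajectory

__all__ = [
    "plot_intensity_kde",
    "plot_stoichiometry_hist",
    "plot_msd_curves",
    "plot_diffusion_hist",
    "plot_trajectory_overlay",
    "plot_two_color",
]


def plot_intensity_kde(intensities: np.ndarray, estimate: IsingleEstimate, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    kde = gaussian_kde(intensities, bw_method=estimate.kde_bandwidth)
    grid = np.linspace(0, float(np.max(intensities)), 1000)
    ax.hist(intensities, bins=40, density=True, alpha=0.4, label="intensities")
    ax.plot(grid, kde(grid), label="KDE")
    ax.axvline(estimate.value, color="k", ls="--",
               label=f"Isingle = {estimate.value:.0f}")
    ax.set_xlabel("background-corrected intensity (counts)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stoichiometry_hist(results: list[StoichiometryResult], path) -> None:
    vals = [r.stoichiometry for r in results]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if vals:
        ax.hist(vals, bins=np.arange(0.25, max(vals) + 1, 0.5))
    ax.set_xlabel("stoichiometry (fluorophores)")
    ax.set_ylabel("trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_msd_curves(curves: list[MSDCurve], path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        ax.plot(c.tau, c.msd, alpha=0.6, lw=0.8)
    ax.set_xlabel("τ (s)")
    ax.set_ylabel("MSD (µm²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diffusion_hist(results: list[DiffusionResult], path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if results:
        ax.hist([r.D for r in results], bins=20)
    ax.set_xlabel("D (µm²/s)")
    ax.set_ylabel("trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory_overlay(frames: np.ndarray, trajectories: list[Trajectory],
                            path, n_mean_frames: int = 5) -> None:
    """Trajectories drawn over the mean of the first bright frames."""
    mean_img = np.asarray(frames[:n_mean_frames], dtype=float).mean(axis=0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(mean_img, cmap="gray", origin="upper")
    for t in trajectories:
        pos = t.positions
        ax.plot(pos[:, 0], pos[:, 1], lw=1.0)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_two_color(frame_left: np.ndarray, frame_right: np.ndarray,
                   pairs: list[ColocalizedPair], path) -> None:
    """Side-by-side channels with matched colors for colocalized foci."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, img in zip(axes, (frame_left, frame_right)):
        ax.imshow(np.asarray(img, dtype=float), cmap="gray", origin="upper")
        ax.set_axis_off()
    cmap = plt.get_cmap("tab10")
    for k, p in enumerate(pairs):
        color = cmap(k % 10)
        axes[0].plot(p.focus_left.x, p.focus_left.y, "o", mfc="none", color=color)
        axes[1].plot(p.focus_right.x, p.focus_right.y, "o", mfc="none", color=color)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
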