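"""Mean squared displacement curves and 2D diffusion coefficients.

For each trajectory the MSD at lag τ = kΔt is the mean of |r(t+kΔt) − r(t)|²
over all overlapping displacement pairs, in µm². For 2D Brownian motion
MSD(τ) = 4Dτ (+ a localization-noise offset), so a weighted straight-line
fit over the first few lags gives D = gradient / 4. The fit is weighted by
the number of displacement pairs per lag, favoring the better-sampled low-τ
points; it is unconstrained by default, or the intercept can be pinned to
4σ² when the localization precision σ is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track import Trajectory

__all__ = ["MSDCurve", "DiffusionResult", "msd", "fit_diffusion", "analyze_diffusion"]


@dataclass
class MSDCurve:
    traj_id: int
    tau: np.ndarray  # s
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray


@dataclass
class DiffusionResult:
    traj_id: int
    D: float  # µm²/s
    intercept: float  # µm²
    n_points_fit: int


def msd(trajectory: Trajectory, pixel_size: float, frame_interval: float,
        max_lag: int | None = None) -> MSDCurve:
    """MSD over all overlapping pairs, for lags 1..len-1 (or ``max_lag``)."""
    pos = trajectory.positions * pixel_size
    n = len(pos)
    if n < 2:
        raise ValueError("trajectory too short for an MSD")
    lags = np.arange(1, n if max_lag is None else min(n, max_lag + 1))
    vals = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for idx, k in enumerate(lags):
        d = pos[k:] - pos[:-k]
        vals[idx] = float((d ** 2).sum(axis=1).mean())
        counts[idx] = n - k
    return MSDCurve(traj_id=trajectory.id, tau=lags * frame_interval,
                    msd=vals, n_pairs=counts)


def fit_diffusion(curve: MSDCurve, n_points_fit: int = 4,
                  localization_precision: float | None = None) -> DiffusionResult:
    """Weighted least-squares line over the first ``n_points_fit`` MSD points.

    Weights are proportional to the pair counts. D = gradient/4. With a
    localization precision σ (µm) the intercept is constrained to 4σ² and
    only the gradient is fit.
    """
    m = min(n_points_fit, len(curve.tau))
    if m < 2 and localization_precision is None:
        raise ValueError("need at least two MSD points for an unconstrained fit")
    if m < 1:
        raise ValueError("empty MSD curve")
    tau = curve.tau[:m]
    y = curve.msd[:m]
    wgt = curve.n_pairs[:m].astype(float)
    if localization_precision is not None:
        c = 4.0 * localization_precision ** 2
        slope = float((wgt * tau * (y - c)).sum() / (wgt * tau ** 2).sum())
        intercept = c
    else:
        W = np.diag(wgt)
        A = np.column_stack([tau, np.ones_like(tau)])
        slope, intercept = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
    return DiffusionResult(traj_id=curve.traj_id, D=float(slope) / 4.0,
                           intercept=float(intercept), n_points_fit=m)


def analyze_diffusion(trajectories: list[Trajectory], pixel_size: float,
                      frame_interval: float, n_points_fit: int = 4,
                      min_traj_len: int = 5,
                      localization_precision: float | None = None
                      ) -> list[DiffusionResult]:
    """Per-trajectory diffusion coefficients.

    Trajectories of ``min_traj_len`` frames or fewer are disregarded (strict
    inequality: the default 5 keeps trajectories of 6+ frames).
    """
    out = []
    for t in trajectories:
        if len(t) <= min_traj_len:
            continue
        out.append(fit_diffusion(msd(t, pixel_size, frame_interval),
                                 n_points_fit=n_points_fit,
                                 localization_precision=localization_precision))
    return out


def diffusion_to_frame(results: list[DiffusionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.traj_id, r.D, r.intercept, r.n_points_fit) for r in results],
        columns=["traj_id", "D", "intercept", "n_points"],
    )
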