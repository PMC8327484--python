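"""Synthetic single-molecule image stacks with known ground truth.

Foci are multi-fluorophore emitters rendered as pixel-integrated 2D Gaussian
point spread functions on a Gaussian camera background. Each fluorophore
photobleaches irreversibly and independently with a fixed per-frame
probability, producing the step-wise intensity decay used for single-
fluorophore brightness (Isingle) and stoichiometry analysis; because a
fluorophore can bleach at any point during a frame exposure, the first frame
in which it is counted "off" receives a uniform-random fraction of Isingle.
Foci optionally diffuse with 2D Brownian steps between frames (they are
static within a frame).

Rod-shaped-cell scenes place emitters uniformly in a 3D spherocylinder
imaged at its midplane: lateral PSF width grows with axial defocus as
sigma(z) = sigma0 * sqrt(1 + (z/z_R)^2) with integrated photons conserved.

All randomness flows through one seeded ``numpy.random.Generator``, so
seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .image_io import CellMask, ImageStack
from .params import RodCellGeometry, SimulationParams

__all__ = [
    "SimulationGroundTruth",
    "simulate_stack",
    "simulate_cell_scene",
    "simulate_two_color",
    "render_gaussian",
    "defocus_correction_factor",
]

GROUND_TRUTH_COLUMNS = ["frame", "spot_id", "x_true", "y_true", "n_active", "partial"]


@dataclass
class SimulationGroundTruth:
    """Per-frame truth for every simulated focus.

    ``table`` has one row per (frame, focus) while the focus still emits:
    true center, active fluorophore count and the partial-bleach fraction
    contributed in that frame. ``n_active`` is non-increasing per focus and a
    fully bleached focus disappears from later frames.
    """

    table: pd.DataFrame
    isingle: float
    diffusion_coeff: float
    initial_stoichiometries: np.ndarray

    def positions(self, frame: int) -> np.ndarray:
        sel = self.table[self.table["frame"] == frame]
        return sel[["x_true", "y_true"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def render_gaussian(frame: np.ndarray, x0: float, y0: float,
                    total: float, sigma: float) -> None:
    """Add a pixel-integrated symmetric 2D Gaussian of integrated intensity
    ``total`` at sub-pixel center (x0, y0), in place.

    Pixel (row r, col c) spans [c-0.5, c+0.5] × [r-0.5, r-0.5+1]; the value
    added is the exact integral of the Gaussian over that square.
    """
    h, w = frame.shape
    ext = int(np.ceil(6 * sigma)) + 1
    c0, c1 = max(0, int(np.floor(x0)) - ext), min(w - 1, int(np.ceil(x0)) + ext)
    r0, r1 = max(0, int(np.floor(y0)) - ext), min(h - 1, int(np.ceil(y0)) + ext)
    if c0 > c1 or r0 > r1:
        return
    s = sigma * np.sqrt(2.0)
    cols = np.arange(c0, c1 + 1, dtype=float)
    rows = np.arange(r0, r1 + 1, dtype=float)
    fx = 0.5 * (erf((cols + 0.5 - x0) / s) - erf((cols - 0.5 - x0) / s))
    fy = 0.5 * (erf((rows + 0.5 - y0) / s) - erf((rows - 0.5 - y0) / s))
    frame[r0:r1 + 1, c0:c1 + 1] += total * np.outer(fy, fx)


def _place_spots(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.frame_size
    m = params.edge_margin
    if w - 1 - 2 * m <= 0 or h - 1 - 2 * m <= 0:
        raise ValueError("edge_margin leaves no room for spot placement")
    pos = np.empty((params.num_spots, 2))
    for i in range(params.num_spots):
        for _ in range(10_000):
            cand = np.array([rng.uniform(m, w - 1 - m), rng.uniform(m, h - 1 - m)])
            if i == 0 or params.min_separation <= 0 or \
                    np.min(np.hypot(*(pos[:i] - cand).T)) >= params.min_separation:
                pos[i] = cand
                break
        else:
            raise ValueError("could not place spots at the requested separation")
    return pos


def _initial_stoichiometries(params: SimulationParams,
                             rng: np.random.Generator) -> np.ndarray:
    if params.stoichiometries is not None:
        n0 = np.asarray(params.stoichiometries, dtype=int)
        if len(n0) != params.num_spots:
            raise ValueError("stoichiometries length must equal num_spots")
        return n0.copy()
    if params.max_stoichiometry == 1:
        return np.ones(params.num_spots, dtype=int)
    return rng.integers(1, params.max_stoichiometry + 1, params.num_spots)


def _finish_frame(clean: np.ndarray, params: SimulationParams,
                  rng: np.random.Generator) -> np.ndarray:
    noisy = clean + rng.normal(params.bg_mean, params.bg_std, clean.shape)
    return np.round(np.clip(noisy, 0.0, None))


def simulate_stack(params: SimulationParams,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ImageStack, SimulationGroundTruth]:
    """Simulate a diffusing, stochastically photobleaching acquisition.

    Returns the quantized noisy stack and its ground truth. Foci leaving the
    frame while diffusing keep their truth records and simply render
    partially or not at all (no reflecting walls).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.frame_size

    if params.initial_positions is not None:
        pos = np.asarray(params.initial_positions, dtype=float).reshape(-1, 2).copy()
        if len(pos) != params.num_spots:
            raise ValueError("initial_positions length must equal num_spots")
    else:
        pos = _place_spots(params, rng)
    n_active = _initial_stoichiometries(params, rng)
    n0 = n_active.copy()

    step_sigma_px = 0.0
    if params.diffusion_coeff > 0:
        step_sigma_px = np.sqrt(2.0 * params.diffusion_coeff
                                * params.frame_interval) / params.pixel_size

    frames = np.zeros((params.num_frames, h, w))
    rows = []
    partial = np.zeros(params.num_spots)
    for t in range(params.num_frames):
        clean = np.zeros((h, w))
        for i in range(params.num_spots):
            if n_active[i] <= 0 and partial[i] == 0.0:
                continue
            total = (n_active[i] + partial[i]) * params.isingle
            render_gaussian(clean, pos[i, 0], pos[i, 1], total, params.psf_sigma)
            rows.append((t, i, pos[i, 0], pos[i, 1], int(n_active[i]), partial[i]))
        frames[t] = _finish_frame(clean, params, rng)

        # bleach step: decide which fluorophores are off from frame t+1;
        # each newly-off fluorophore emits a uniform fraction of isingle in
        # that first off frame (it bleached partway through the exposure).
        partial = np.zeros(params.num_spots)
        if params.p_bleach_per_frame > 0:
            for i in range(params.num_spots):
                if n_active[i] > 0:
                    k = rng.binomial(n_active[i], params.p_bleach_per_frame)
                    if k > 0:
                        n_active[i] -= k
                        partial[i] = float(rng.uniform(0.0, 1.0, k).sum())
        # diffusion step at the end of the frame (static during exposure)
        if step_sigma_px > 0:
            alive = n_active > 0
            steps = rng.normal(0.0, step_sigma_px, (params.num_spots, 2))
            pos[alive] += steps[alive]

    table = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    stack = ImageStack(frames=frames, pixel_size=params.pixel_size,
                       frame_interval=params.frame_interval)
    truth = SimulationGroundTruth(table=table, isingle=params.isingle,
                                  diffusion_coeff=params.diffusion_coeff,
                                  initial_stoichiometries=n0)
    return stack, truth


# rod-shaped cell scenes -----------------------------------------------------

def _sample_rod_volume(n: int, geometry: RodCellGeometry,
                       rng: np.random.Generator) -> np.ndarray:
    """Uniform points (x, y, z) in µm inside a spherocylinder centered at the
    origin with axis along x (rejection sampling in the bounding box)."""
    half = geometry.length_um / 2.0
    r = geometry.radius_um
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = 4 * (n - got) + 16
        pts = rng.uniform(-1.0, 1.0, (m, 3)) * np.array([half, r, r])
        ax = np.clip(np.abs(pts[:, 0]) - (half - r), 0.0, None)
        inside = ax ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2 <= r ** 2
        take = pts[inside][: n - got]
        out[got:got + len(take)] = take
        got += len(take)
    return out


def rod_mask(geometry: RodCellGeometry, params: SimulationParams) -> CellMask:
    """Binary mask of the rod's 2D projection (label 1)."""
    h, w = params.frame_size
    cx, cy = geometry.center(params.frame_size)
    half = geometry.length_um / 2.0 / params.pixel_size
    r = geometry.radius_um / params.pixel_size
    xg, yg = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    ax = np.clip(np.abs(xg - cx) - (half - r), 0.0, None)
    labels = ((ax ** 2 + (yg - cy) ** 2) <= r ** 2).astype(np.int64)
    return CellMask(labels=labels)


def _defocus_sigma(z_um: float, params: SimulationParams) -> float:
    return params.psf_sigma * np.sqrt(1.0 + (z_um / params.psf_axial_range_um) ** 2)


def simulate_cell_scene(n_fluorophores: int, geometry: RodCellGeometry,
                        params: SimulationParams,
                        rng: np.random.Generator | None = None,
                        midplane_only: bool = False
                        ) -> tuple[ImageStack, CellMask, SimulationGroundTruth]:
    """Immobile fluorophores uniform in a 3D rod cell, imaged at midplane.

    Each emitter is rendered with the defocus-broadened lateral width for its
    axial position; integrated photons are conserved, so out-of-focus light
    spreads (partly beyond the cell mask) rather than vanishing.
    ``midplane_only`` clamps every emitter to the focal plane (z = 0), the
    in-focus limit useful for validating the copy-number estimator.
    """
    params.validate()
    geometry.validate(params.pixel_size, params.frame_size)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.frame_size
    cx, cy = geometry.center(params.frame_size)

    pts = _sample_rod_volume(n_fluorophores, geometry, rng)
    if midplane_only:
        pts[:, 2] = 0.0
    xs = cx + pts[:, 0] / params.pixel_size
    ys = cy + pts[:, 1] / params.pixel_size
    zs = pts[:, 2]

    frames = np.zeros((params.num_frames, h, w))
    clean = np.zeros((h, w))
    rows = []
    for i in range(n_fluorophores):
        render_gaussian(clean, xs[i], ys[i], params.isingle,
                        _defocus_sigma(zs[i], params))
        rows.append((0, i, xs[i], ys[i], 1, 0.0))
    for t in range(params.num_frames):
        frames[t] = _finish_frame(clean, params, rng)

    table = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    stack = ImageStack(frames=frames, pixel_size=params.pixel_size,
                       frame_interval=params.frame_interval)
    truth = SimulationGroundTruth(table=table, isingle=params.isingle,
                                  diffusion_coeff=0.0,
                                  initial_stoichiometries=np.ones(n_fluorophores, int))
    return stack, rod_mask(geometry, params), truth


def defocus_correction_factor(geometry: RodCellGeometry, params: SimulationParams,
                              n_samples: int = 2000,
                              seed: int = 0, midplane_only: bool = False) -> float:
    """Out-of-focal-plane correction for whole-cell copy numbers.

    Monte-Carlo estimate, under the same defocus model the simulator uses, of
    (total emitted)/(expected detected inside the cell mask) for emitters
    uniform in the rod volume: defocused, broadened PSFs leak light outside
    the mask, so masked integration under-counts and the factor is > 1.
    """
    rng = np.random.default_rng(seed)
    mask = rod_mask(geometry, params).labels.astype(bool)
    h, w = params.frame_size
    cx, cy = geometry.center(params.frame_size)
    pts = _sample_rod_volume(n_samples, geometry, rng)
    if midplane_only:
        pts[:, 2] = 0.0
    frac = np.empty(n_samples)
    frame = np.zeros((h, w))
    for i in range(n_samples):
        frame[:] = 0.0
        render_gaussian(frame, cx + pts[i, 0] / params.pixel_size,
                        cy + pts[i, 1] / params.pixel_size,
                        1.0, _defocus_sigma(pts[i, 2], params))
        frac[i] = frame[mask].sum()
    return float(1.0 / frac.mean())


# two-color scenes -----------------------------------------------------------

def simulate_two_color(params_left: SimulationParams,
                       params_right: SimulationParams,
                       colocalized_fraction: float,
                       rng: np.random.Generator | None = None):
    """Two perfectly-registered channels sharing a stated fraction of foci.

    The first round(colocalized_fraction * num_spots) foci of each channel
    are placed at identical positions; the rest are independent. Returns
    (stack_left, stack_right, truth_left, truth_right, n_colocalized).
    """
    if params_left.frame_size != params_right.frame_size:
        raise ValueError("channels must share frame geometry")
    if not (0.0 <= colocalized_fraction <= 1.0):
        raise ValueError("colocalized_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(params_left.seed)

    n_shared = int(round(colocalized_fraction * min(params_left.num_spots,
                                                    params_right.num_spots)))
    # draw one joint layout so shared foci coincide and all spots (in both
    # channels) respect the min-separation constraint
    n_total = params_left.num_spots + params_right.num_spots - n_shared
    layout = _place_spots(replace(params_left, num_spots=n_total), rng)
    pos_left = np.vstack([layout[:n_shared],
                          layout[n_shared:params_left.num_spots]])
    pos_right = np.vstack([layout[:n_shared],
                           layout[params_left.num_spots:]])

    left = replace(params_left, initial_positions=pos_left)
    right = replace(params_right, initial_positions=pos_right)
    stack_l, truth_l = simulate_stack(left, rng)
    stack_r, truth_r = simulate_stack(right, rng)
    return stack_l, stack_r, truth_l, truth_r, n_shared
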