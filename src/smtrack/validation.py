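"""Ground-truth benchmark routines.

Each function builds a synthetic acquisition with the simulator, runs the
full analysis pipeline on it and measures how well a known input quantity is
recovered. They serve as end-to-end self-tests of the detection → tracking →
post-processing chain under the standard simulation conditions (10 foci of
10,000 counts on a 500 ± 120-count background in a 128×128 field, 120 nm
pixels) and are used by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import DetectionParams, detect_frame
from .diffusion import analyze_diffusion
from .intensity import estimate_isingle, pool_intensities, stoichiometries
from .params import LinkingParams, RodCellGeometry, SimulationParams
from .simulate import defocus_correction_factor, simulate_cell_scene, simulate_stack
from .track import build_trajectories

__all__ = [
    "optimal_detection_params",
    "detection_completeness",
    "isingle_recovery",
    "stoichiometry_range",
    "localization_error_mode",
    "copy_number_recovery",
    "diffusion_recovery",
]


def _rng_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % 2**31)


def optimal_detection_params() -> DetectionParams:
    """The well-optimized detection parameter set for the default
    simulation conditions."""
    return DetectionParams(snr_filter_cutoff=0.4, bw_threshold_tolerance=0.8,
                           subarray_halfwidth=8, inner_mask_radius=3,
                           filter_image="gaussian")


def detection_completeness(seed: int = 0) -> tuple[int, int]:
    """(matched detections, true foci) on one default two-frame acquisition.

    A detection counts as matched when it lies within 2 px of a distinct
    ground-truth focus, and every detection must survive linking into a
    2-frame trajectory (max_displacement 7, min_traj_len 2).
    """
    params = SimulationParams(num_frames=2, seed=seed)
    stack, truth = simulate_stack(params)
    det = optimal_detection_params()
    foci = [detect_frame(stack.frames[t], det, t) for t in range(2)]
    trajs = build_trajectories(foci, LinkingParams(max_displacement=7.0,
                                                   min_traj_len=2))
    gt = truth.positions(0)
    matched = set()
    for t in trajs:
        f = t.foci[0]
        d = np.hypot(gt[:, 0] - f.x, gt[:, 1] - f.y)
        if d.min() <= 2.0:
            matched.add(int(d.argmin()))
    return len(matched), params.num_spots


def _track(stack, det: DetectionParams, link: LinkingParams):
    foci = [detect_frame(stack.frames[t], det, t)
            for t in range(stack.num_frames)]
    return build_trajectories(foci, link)


def isingle_recovery(seed: int = 0, isingle: float = 14_000.0,
                     n_replicates: int = 3, num_frames: int = 100,
                     p_bleach: float = 0.05, max_stoichiometry: int = 10) -> float:
    """KDE-peak Isingle from simulated step-wise photobleaching stacks.

    Immobile multi-fluorophore foci bleach stochastically; pooled
    background-corrected intensities from the final half of the acquisition
    (mostly bleached down to single fluorophores) feed the bandwidth-0.7
    Gaussian KDE whose global peak estimates Isingle.
    """
    det = optimal_detection_params()
    link = LinkingParams(max_displacement=5.0, min_traj_len=3)
    pooled = []
    for r in range(n_replicates):
        p = SimulationParams(isingle=isingle, max_stoichiometry=max_stoichiometry,
                             p_bleach_per_frame=p_bleach, diffusion_coeff=0.0,
                             num_frames=num_frames, seed=_rng_seed(seed, r))
        stack, _ = simulate_stack(p)
        trajs = _track(stack, det, link)
        pooled.append(pool_intensities(trajs, num_frames=num_frames,
                                       use_last_half=True))
    return float(estimate_isingle(np.concatenate(pooled), bandwidth=0.7).value)


def stoichiometry_range(seed: int = 0, max_n: int = 25,
                        isingle: float = 14_000.0) -> dict[int, int]:
    """Recovered rounded stoichiometry for inputs 1..max_n.

    One immobile, non-bleaching focus per stoichiometry on a grid, default
    background noise; recovery uses the trajectory-linked intensities and the
    known Isingle.
    """
    side = int(np.ceil(np.sqrt(max_n)))
    h = w = max(128, 22 * side + 6)
    xs = np.linspace(14, w - 15, side)
    pos = [(float(x), float(y)) for y in xs for x in xs][:max_n]
    p = SimulationParams(isingle=isingle, num_spots=max_n, num_frames=8,
                         frame_size=(h, w), diffusion_coeff=0.0,
                         initial_positions=pos,
                         stoichiometries=list(range(1, max_n + 1)),
                         seed=seed)
    stack, truth = simulate_stack(p)
    trajs = _track(stack, optimal_detection_params(),
                   LinkingParams(max_displacement=5.0, min_traj_len=4))
    results = stoichiometries(trajs, isingle)
    out: dict[int, int] = {}
    gt = np.asarray(pos)
    by_id = {t.id: t for t in trajs}
    for r in results:
        f0 = by_id[r.traj_id].foci[0]
        i = int(np.argmin(np.hypot(gt[:, 0] - f0.x, gt[:, 1] - f0.y)))
        out[i + 1] = r.rounded
    return out


def localization_error_mode(seed: int = 0, n_sims: int = 20,
                            n_frames: int = 10, bin_width: float = 0.05) -> float:
    """Modal localization error (pixels) over default simulations.

    Detections are matched to ground truth within 2 px; the error magnitudes
    are histogrammed in ``bin_width``-px bins and the modal bin center
    returned.
    """
    det = optimal_detection_params()
    errs = []
    for s in range(n_sims):
        p = SimulationParams(num_frames=n_frames, seed=_rng_seed(seed, 100 + s))
        stack, truth = simulate_stack(p)
        for t in range(n_frames):
            gt = truth.positions(t)
            if not len(gt):
                continue
            for f in detect_frame(stack.frames[t], det, t):
                d = float(np.hypot(gt[:, 0] - f.x, gt[:, 1] - f.y).min())
                if d <= 2.0:
                    errs.append(d)
    hist, edges = np.histogram(errs, bins=np.arange(0.0, 2.0 + bin_width, bin_width))
    return float(edges[int(np.argmax(hist))] + bin_width / 2.0)


def copy_number_recovery(seed: int = 0, n_scenes: int = 10,
                         n_fluorophores: int = 100) -> tuple[float, float, list[float]]:
    """(mean, SEM, values) of corrected whole-cell copy numbers.

    Each scene is one rod-shaped cell with ``n_fluorophores`` emitters
    uniform in its 3D volume, imaged at the midplane; the estimate is the
    masked background-corrected intensity of the first frame divided by the
    known Isingle, times the defocus correction factor computed from the same
    optical model.
    """
    from .intensity import copy_number

    geom = RodCellGeometry()
    base = SimulationParams(num_frames=1)
    corr = defocus_correction_factor(geom, base, n_samples=2000,
                                     seed=_rng_seed(seed, 200))
    values = []
    for s in range(n_scenes):
        p = SimulationParams(num_frames=1, seed=_rng_seed(seed, 201 + s))
        stack, mask, _ = simulate_cell_scene(n_fluorophores, geom, p)
        values.append(copy_number(stack, mask, isingle=p.isingle,
                                  correction=corr)[1])
    values = [float(v) for v in values]
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr))), values


def diffusion_recovery(seed: int = 0, n_sims: int = 10,
                       d_input: float = 1.0) -> tuple[float, float, np.ndarray]:
    """(mean, SEM, all per-trajectory estimates) for default diffusing
    simulations at ``d_input`` µm²/s, 100 frames each.

    Tracking uses the 7-px linking cutoff; trajectories of 5 frames or fewer
    are disregarded and D comes from the pair-count-weighted fit of the first
    four MSD points.
    """
    det = optimal_detection_params()
    link = LinkingParams(max_displacement=7.0, min_traj_len=3)
    ds = []
    for s in range(n_sims):
        p = SimulationParams(diffusion_coeff=d_input,
                             seed=_rng_seed(seed, 300 + s))
        stack, _ = simulate_stack(p)
        trajs = _track(stack, det, link)
        ds += [r.D for r in analyze_diffusion(trajs, p.pixel_size,
                                              p.frame_interval,
                                              min_traj_len=5)]
    ds = np.asarray(ds, dtype=float)
    return float(ds.mean()), float(ds.std(ddof=1) / np.sqrt(len(ds))), ds
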