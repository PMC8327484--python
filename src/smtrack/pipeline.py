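"""High-level tasks tying the stages together around a file root.

Every task reads and writes files named ``<file_root>_*``: ``simulate``
produces ``<root>.tif`` and a ground-truth CSV, ``track`` produces the
trajectory CSV, ``postprocess`` the Isingle/stoichiometry/diffusion tables
and plots, and ``view`` a trajectory overlay image. The command line is a
thin wrapper over these functions; they are equally usable from Python.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import diffusion as diff
from . import intensity as inten
from . import plots
from .detect import detect_stack
from .image_io import (ImageStack, read_stack, read_trajectories, write_stack,
                       write_trajectories)
from .params import Parameters
from .simulate import simulate_stack
from .track import build_trajectories

log = logging.getLogger("smtrack")

__all__ = ["task_simulate", "task_track", "task_postprocess", "task_view",
           "track_stack"]


def task_simulate(file_root: str, params: Parameters) -> None:
    stack, truth = simulate_stack(params.simulation)
    out = np.clip(stack.frames, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    write_stack(ImageStack(out, stack.pixel_size, stack.frame_interval),
                f"{file_root}.tif")
    truth.to_csv(f"{file_root}_ground_truth.csv")
    log.info("simulate: wrote %s.tif (%d frames, %d spots)", file_root,
             params.simulation.num_frames, params.simulation.num_spots)


def track_stack(stack: ImageStack, params: Parameters):
    """Detect every frame and link into trajectories."""
    foci = detect_stack(stack.frames, params.detection, num_procs=params.num_procs)
    return build_trajectories(foci, params.linking)


def task_track(file_root: str, params: Parameters) -> None:
    stack = read_stack(f"{file_root}.tif",
                       pixel_size=params.simulation.pixel_size,
                       frame_interval=params.simulation.frame_interval)
    trajectories = track_stack(stack, params)
    write_trajectories(trajectories, f"{file_root}_trajectories.csv")
    log.info("track: %d trajectories from %d frames", len(trajectories),
             stack.num_frames)


def task_postprocess(file_root: str, params: Parameters) -> None:
    trajectories = read_trajectories(f"{file_root}_trajectories.csv")
    sim = params.simulation
    root = Path(file_root)

    intensities = inten.pool_intensities(trajectories,
                                         use_last_half=params.use_last_half)
    if intensities.size >= 10:
        est = inten.estimate_isingle(intensities, bandwidth=params.kde_bandwidth)
        isingle = est.value
        plots.plot_intensity_kde(intensities, est, f"{root}_intensity_kde.png")
        log.info("postprocess: Isingle = %.0f ± %.0f counts", est.value,
                 est.half_width)
    else:
        isingle = sim.isingle
        log.info("postprocess: too few foci for a KDE; using configured "
                 "isingle = %.0f", isingle)

    stoich = inten.stoichiometries(trajectories, isingle)
    inten.stoichiometries_to_frame(stoich).to_csv(
        f"{root}_stoichiometry.csv", index=False, float_format="%.10g")
    plots.plot_stoichiometry_hist(stoich, f"{root}_stoichiometry_hist.png")

    results = diff.analyze_diffusion(
        trajectories, sim.pixel_size, sim.frame_interval,
        n_points_fit=params.msd_fit_points,
        min_traj_len=params.min_traj_len_diffusion,
        localization_precision=params.localization_precision)
    diff.diffusion_to_frame(results).to_csv(
        f"{root}_diffusion.csv", index=False, float_format="%.10g")
    curves = [diff.msd(t, sim.pixel_size, sim.frame_interval)
              for t in trajectories if len(t) > params.min_traj_len_diffusion]
    plots.plot_msd_curves(curves, f"{root}_msd.png")
    plots.plot_diffusion_hist(results, f"{root}_diffusion_hist.png")
    log.info("postprocess: %d stoichiometries, %d diffusion fits",
             len(stoich), len(results))


def task_view(file_root: str, params: Parameters) -> None:
    stack = read_stack(f"{file_root}.tif",
                       pixel_size=params.simulation.pixel_size,
                       frame_interval=params.simulation.frame_interval)
    trajectories = read_trajectories(f"{file_root}_trajectories.csv")
    plots.plot_trajectory_overlay(stack.frames, trajectories,
                                  f"{file_root}_overlay.png")
    log.info("view: wrote %s_overlay.png", file_root)
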