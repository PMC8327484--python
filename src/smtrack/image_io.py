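"""TIFF stack / cell-mask input and trajectory-table output.

Image stacks are plain single- or multi-page grayscale TIFFs; acquisition
calibration (pixel size, frame interval) is never read from TIFF metadata —
it always comes from configuration. Trajectory tables are comma-delimited
text with the fixed header ``traj_id,frame,x,y,intensity,width_x,width_y,snr``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import Focus
from .track import Trajectory

__all__ = [
    "ImageStack",
    "CellMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_trajectories",
    "read_trajectories",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = ["traj_id", "frame", "x", "y", "intensity",
                      "width_x", "width_y", "snr"]


@dataclass
class ImageStack:
    """A T×H×W stack of pixel intensities with acquisition calibration."""

    frames: np.ndarray  # T×H×W, counts
    pixel_size: float  # µm / pixel
    frame_interval: float  # s / frame

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3 or 0 in self.frames.shape:
            raise ValueError("frames must be a non-empty T×H×W array")
        if float(self.frames.min()) < 0:
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def num_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class CellMask:
    """Labelled segmentation: 0 = background, k >= 1 = pixels of cell k."""

    labels: np.ndarray  # H×W integer

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(int(k) for k in np.unique(self.labels) if k > 0)


def read_stack(path, pixel_size: float = 0.120,
               frame_interval: float = 0.005) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Calibration is supplied by the caller (configuration), never parsed from
    the file. Color (RGB) or mixed-shape TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {frames.shape}")
    if frames.shape[-1] in (3, 4) and frames.shape[-1] < min(frames.shape[:-1]):
        raise ValueError(f"{path}: RGB/RGBA TIFF is not a grayscale stack")
    return ImageStack(frames=frames, pixel_size=pixel_size,
                      frame_interval=frame_interval)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(str(path), stack.frames)


def read_mask(path) -> CellMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = tifffile.imread(str(path))
    if labels.ndim == 3 and labels.shape[0] == 1:
        labels = labels[0]
    return CellMask(labels=labels.astype(np.int64))


def write_mask(mask: CellMask, path) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = [
        (t.id, f.frame, f.x, f.y, f.intensity, f.width_x, f.width_y, f.snr)
        for t in trajectories for f in t.foci
    ]
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write one CSV row per (trajectory, frame); empty input writes the
    header only. Floats keep full precision for loss-free post-processing."""
    df = trajectories_to_frame(trajectories)
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectories(path) -> list[Trajectory]:
    """Rebuild :class:`Trajectory` objects from a trajectory CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for traj_id, group in df.groupby("traj_id", sort=True):
        group = group.sort_values("frame")
        foci = [
            Focus(frame=int(r.frame), x=float(r.x), y=float(r.y),
                  intensity=float(r.intensity), width_x=float(r.width_x),
                  width_y=float(r.width_y), snr=float(r.snr))
            for r in group.itertuples()
        ]
        out.append(Trajectory(id=int(traj_id), foci=foci))
    return out
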