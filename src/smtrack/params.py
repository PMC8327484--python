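"""Named tunable parameters with experiment-calibrated defaults.

All spatial parameters are in pixel units unless the name says otherwise;
intensities are in camera counts. ``Parameters`` is the flat, override-able
bag used by the command line; the per-stage dataclasses are the typed views
the library functions take.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimulationParams",
    "DetectionParams",
    "LinkingParams",
    "RodCellGeometry",
    "Parameters",
]


@dataclass
class SimulationParams:
    """Conditions of a synthetic single-molecule acquisition.

    isingle
        Integrated counts emitted by one fluorophore per frame.
    bg_mean, bg_std
        Gaussian camera background (counts).
    diffusion_coeff
        2D diffusion coefficient in µm²/s; 0 for immobile foci.
    p_bleach_per_frame
        Per-fluorophore, per-frame irreversible photobleach probability
        (mean bleach time = 1/p frames).
    max_stoichiometry
        Initial fluorophores per focus drawn uniformly in [1, max]; 1 means
        every focus is a single fluorophore.
    psf_sigma
        Gaussian point-spread-function width (pixels), ~FWHM 3 px for GFP
        imaged at 120 nm/pixel.
    edge_margin, min_separation
        Placement constraints (pixels) producing the sparse, fully-in-frame
        fields the tracking method is designed for; set both to 0 for
        unconstrained uniform placement.
    psf_axial_range_um
        Axial range z_R of the defocus model sigma(z) = psf_sigma *
        sqrt(1 + (z/z_R)^2) used for 3D cell scenes.
    """

    isingle: float = 10_000.0
    bg_mean: float = 500.0
    bg_std: float = 120.0
    num_spots: int = 10
    frame_size: tuple[int, int] = (128, 128)  # (H, W)
    num_frames: int = 100
    diffusion_coeff: float = 1.0
    pixel_size: float = 0.120  # µm / pixel
    frame_interval: float = 0.005  # s / frame
    max_stoichiometry: int = 1
    p_bleach_per_frame: float = 0.0
    psf_sigma: float = 1.33
    edge_margin: float = 10.0
    min_separation: float = 10.0
    psf_axial_range_um: float = 0.6
    seed: Optional[int] = None
    # optional explicit ground truth, overriding random placement
    initial_positions: Optional[Sequence[tuple[float, float]]] = None
    stoichiometries: Optional[Sequence[int]] = None

    def validate(self) -> None:
        if self.isingle <= 0:
            raise ValueError("isingle must be > 0")
        if self.bg_std < 0:
            raise ValueError("bg_std must be >= 0")
        if self.num_spots < 0:
            raise ValueError("num_spots must be >= 0")
        if not (0.0 <= self.p_bleach_per_frame <= 1.0):
            raise ValueError("p_bleach_per_frame must be in [0, 1]")
        if self.max_stoichiometry < 1:
            raise ValueError("max_stoichiometry must be >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        h, w = self.frame_size
        if min(h, w) < int(np.ceil(6 * self.psf_sigma)):
            raise ValueError("frame_size too small to contain a PSF sub-array")


@dataclass
class DetectionParams:
    """Focus detection, sub-pixel localization and SNR filtering.

    The local analysis square is (2*subarray_halfwidth + 1) wide (17x17 at
    the default 8). ``inner_mask_radius`` sets the width of the iterative
    Gaussian mask; ``intensity_radius`` is the circle over which the
    background-corrected intensity is integrated (the two are exposed
    separately).
    """

    filter_image: str = "gaussian"  # "gaussian" or "none"
    filter_sigma: float = 1.0
    struct_disk_radius: int = 10
    bw_threshold_tolerance: float = 0.8
    subarray_halfwidth: int = 8
    inner_mask_radius: float = 3.0
    intensity_radius: float = 5.0
    gauss_mask_sigma: Optional[float] = None  # default: inner_mask_radius
    snr_filter_cutoff: float = 0.4
    max_iterations: int = 1000
    convergence_tol: float = 0.01
    merge_radius: float = 1.0

    @property
    def mask_sigma(self) -> float:
        return self.gauss_mask_sigma if self.gauss_mask_sigma is not None else self.inner_mask_radius

    def validate(self) -> None:
        if self.filter_image not in ("gaussian", "none"):
            raise ValueError("filter_image must be 'gaussian' or 'none'")
        if self.subarray_halfwidth < 1:
            raise ValueError("subarray_halfwidth must be >= 1")
        if self.intensity_radius >= np.hypot(self.subarray_halfwidth, self.subarray_halfwidth):
            raise ValueError("intensity_radius leaves no background pixels in the subarray")


@dataclass
class LinkingParams:
    max_displacement: float = 5.0  # pixels
    min_traj_len: int = 3  # frames

    def validate(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.min_traj_len < 1:
            raise ValueError("min_traj_len must be >= 1")


@dataclass
class RodCellGeometry:
    """Rod-shaped (spherocylindrical) cell: a cylinder of radius ``radius_um``
    along x with hemispherical caps; total tip-to-tip length ``length_um``.
    Centered at ``center_px`` (x, y) in the image, axis parallel to x.
    """

    length_um: float = 3.0
    radius_um: float = 0.5
    center_px: Optional[tuple[float, float]] = None

    def validate(self, pixel_size: float, frame_size: tuple[int, int]) -> None:
        if self.length_um < 2 * self.radius_um:
            raise ValueError("rod length must be at least its diameter")
        h, w = frame_size
        half_len_px = 0.5 * self.length_um / pixel_size
        rad_px = self.radius_um / pixel_size
        cx, cy = self.center(frame_size)
        if (cx - half_len_px < 0 or cx + half_len_px > w - 1
                or cy - rad_px < 0 or cy + rad_px > h - 1):
            raise ValueError("rod cell does not fit inside the frame")

    def center(self, frame_size: tuple[int, int]) -> tuple[float, float]:
        if self.center_px is not None:
            return self.center_px
        h, w = frame_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


# flat parameter bag for the CLI -------------------------------------------

_SIM_FIELDS = {f.name for f in fields(SimulationParams)}
_DET_FIELDS = {f.name for f in fields(DetectionParams)}
_LINK_FIELDS = {f.name for f in fields(LinkingParams)}


@dataclass
class Parameters:
    """Flat collection of every named tunable, with CLI override support."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    # post-processing knobs
    kde_bandwidth: float = 0.7
    use_last_half: bool = False
    ck_window: int = 3
    ck_exponent: float = 1.0
    msd_fit_points: int = 4
    min_traj_len_diffusion: int = 5  # strictly-greater-than cutoff (frames)
    localization_precision: Optional[float] = None  # µm, constrains MSD intercept
    coloc_distance_cutoff: float = 5.0
    overlap_threshold: float = 0.75
    copy_number_correction: Optional[float] = None  # None: compute from defocus model
    num_procs: int = 1

    _TOP_LEVEL = (
        "kde_bandwidth", "use_last_half", "ck_window", "ck_exponent",
        "msd_fit_points", "min_traj_len_diffusion", "localization_precision",
        "coloc_distance_cutoff", "overlap_threshold", "copy_number_correction",
        "num_procs",
    )

    def with_overrides(self, overrides: dict[str, str]) -> "Parameters":
        """Return a copy with ``key=value`` string overrides applied.

        Unknown keys raise KeyError; values are coerced to the target type.
        """
        sim, det, link = dict(), dict(), dict()
        top = dict()
        for key, raw in overrides.items():
            if key in _SIM_FIELDS:
                sim[key] = _coerce(raw, getattr(self.simulation, key), key)
            elif key in _DET_FIELDS:
                det[key] = _coerce(raw, getattr(self.detection, key), key)
            elif key in _LINK_FIELDS:
                link[key] = _coerce(raw, getattr(self.linking, key), key)
            elif key in self._TOP_LEVEL:
                top[key] = _coerce(raw, getattr(self, key), key)
            else:
                raise KeyError(f"unknown parameter: {key!r}")
        return replace(
            self,
            simulation=replace(self.simulation, **sim),
            detection=replace(self.detection, **det),
            linking=replace(self.linking, **link),
            **top,
        )


def _coerce(raw, current, key):
    """Coerce a string override to the type of the current value."""
    if not isinstance(raw, str):
        return raw
    if key == "frame_size":
        parts = raw.strip("()[] ").replace(",", " ").split()
        return (int(parts[0]), int(parts[1]))
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes", "on")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if current is None:
        # optional numerics (seed, localization_precision, ...)
        if raw.lower() in ("none", "null"):
            return None
        try:
            return int(raw)
        except ValueError:
            return float(raw)
    return raw
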