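"""Two-color focus pairing by distance cutoff and Gaussian overlap.

Channels are assumed registered (true for simulated data). Per frame,
candidate pairs within the distance cutoff are scored with the overlap
integral of two symmetric 2D Gaussians at the foci's fitted widths,

    overlap = exp(-d² / (2 (σ₁² + σ₂²))),

the normalized cross-correlation of the two profiles: 1 at zero separation
and strictly decreasing with distance. Pairs at or above the overlap
threshold are kept, each focus in at most one pair (greedy by overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Focus

__all__ = ["ColocalizedPair", "gaussian_overlap", "pair_channels"]


@dataclass
class ColocalizedPair:
    frame: int
    index_left: int
    index_right: int
    focus_left: Focus
    focus_right: Focus
    distance: float  # pixels
    overlap: float  # in [0, 1]


def _mean_width(f: Focus) -> float:
    w = np.nanmean([f.width_x, f.width_y])
    return float(w) if np.isfinite(w) and w > 0 else 1.0


def gaussian_overlap(d: float, sigma1: float, sigma2: float) -> float:
    return float(np.exp(-d ** 2 / (2.0 * (sigma1 ** 2 + sigma2 ** 2))))


def pair_channels(foci_left: list[list[Focus]], foci_right: list[list[Focus]],
                  distance_cutoff: float = 5.0,
                  overlap_threshold: float = 0.75) -> list[ColocalizedPair]:
    """Colocalized pairs per frame across two detected channels."""
    pairs: list[ColocalizedPair] = []
    for t in range(min(len(foci_left), len(foci_right))):
        cands = []
        for i, fl in enumerate(foci_left[t]):
            for j, fr in enumerate(foci_right[t]):
                d = float(np.hypot(fl.x - fr.x, fl.y - fr.y))
                if d > distance_cutoff:
                    continue
                ov = gaussian_overlap(d, _mean_width(fl), _mean_width(fr))
                if ov >= overlap_threshold:
                    cands.append((ov, d, i, j))
        cands.sort(key=lambda c: (-c[0], c[2], c[3]))
        used_i, used_j = set(), set()
        for ov, d, i, j in cands:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            pairs.append(ColocalizedPair(frame=t, index_left=i, index_right=j,
                                         focus_left=foci_left[t][i],
                                         focus_right=foci_right[t][j],
                                         distance=d, overlap=ov))
    return pairs


def pairs_to_frame(pairs: list[ColocalizedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.frame, p.index_left, p.index_right, p.distance, p.overlap) for p in pairs],
        columns=["frame", "left_id", "right_id", "distance", "overlap"],
    )
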