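"""Strict nearest-neighbour trajectory linking.

Foci in consecutive frames are linked when their centers are within
``max_displacement`` pixels. Linking is deliberately conservative: there is
no dropped-frame bridging, and any ambiguity (two trajectories competing for
one detection, or one trajectory facing two mutually-close detections)
terminates the trajectories involved rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Focus
from .params import LinkingParams

__all__ = ["Trajectory", "link_frames", "build_trajectories"]


@dataclass
class Trajectory:
    """An identity maintained over strictly consecutive frames."""

    id: int
    foci: list[Focus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.foci])

    @property
    def positions(self) -> np.ndarray:
        """N×2 array of (x, y) centers in pixels."""
        return np.array([[f.x, f.y] for f in self.foci], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.intensity for f in self.foci], dtype=float)


def link_frames(foci_t: list[Focus], foci_t1: list[Focus],
                params: LinkingParams) -> list[tuple[int, int]]:
    """Links (index_t, index_t1) between two consecutive frames' foci.

    Candidate pairs are within ``max_displacement``. A next-frame focus with
    two or more candidates in frame t is a collision: none of its candidates
    link (both trajectories terminate). Likewise a frame-t focus whose
    candidate partners are themselves within the cutoff of each other is
    ambiguous and links to neither. Remaining candidates are assigned
    greedily by ascending distance (ties by lower focus index).
    """
    params.validate()
    if not foci_t or not foci_t1:
        return []
    a = np.array([[f.x, f.y] for f in foci_t])
    b = np.array([[f.x, f.y] for f in foci_t1])
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    cand = d <= params.max_displacement

    ok_i = np.ones(len(foci_t), dtype=bool)
    ok_j = np.ones(len(foci_t1), dtype=bool)
    # collision: one next-frame focus reachable by >= 2 current foci
    for j in range(len(foci_t1)):
        if cand[:, j].sum() >= 2:
            ok_j[j] = False
            ok_i[cand[:, j]] = False
    # ambiguity: one current focus reaching >= 2 mutually-close next foci
    db = np.sqrt(((b[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    for i in range(len(foci_t)):
        js = np.flatnonzero(cand[i])
        if len(js) >= 2:
            sub = db[np.ix_(js, js)]
            if np.any(sub[np.triu_indices(len(js), k=1)] <= params.max_displacement):
                ok_i[i] = False
                ok_j[js] = False

    pairs = [(d[i, j], i, j) for i in np.flatnonzero(ok_i)
             for j in np.flatnonzero(ok_j) if cand[i, j]]
    pairs.sort()
    links, used_i, used_j = [], set(), set()
    for _, i, j in pairs:
        if i not in used_i and j not in used_j:
            links.append((i, j))
            used_i.add(i)
            used_j.add(j)
    return links


def build_trajectories(foci_per_frame: list[list[Focus]],
                       params: LinkingParams) -> list[Trajectory]:
    """Chain per-frame links into trajectories.

    Unlinked detections start new trajectories; trajectories shorter than
    ``min_traj_len`` frames are discarded from the output.
    """
    params.validate()
    trajectories: list[Trajectory] = []
    next_id = 0
    active: dict[int, Trajectory] = {}  # focus index in current frame -> traj

    for t, foci in enumerate(foci_per_frame):
        if t == 0:
            prev = foci
            for i, f in enumerate(foci):
                traj = Trajectory(id=next_id, foci=[f])
                next_id += 1
                trajectories.append(traj)
                active[i] = traj
            continue
        links = dict(link_frames(prev, foci, params))
        new_active: dict[int, Trajectory] = {}
        linked_j = set()
        for i, j in links.items():
            if i in active:
                active[i].foci.append(foci[j])
                new_active[j] = active[i]
                linked_j.add(j)
        for j, f in enumerate(foci):
            if j not in linked_j:
                traj = Trajectory(id=next_id, foci=[f])
                next_id += 1
                trajectories.append(traj)
                new_active[j] = traj
        active = new_active
        prev = foci

    return [t for t in trajectories if len(t) >= params.min_traj_len]
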