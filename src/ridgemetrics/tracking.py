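"""Frame-to-frame object linkage by minimum-cost assignment under a cutoff.

Cells (cutoff 2.5 µm) and, later, individual ridges (cutoff 2.3 µm) are
linked between consecutive frames by solving a linear assignment problem on
the Euclidean centroid-distance matrix.  Pairs farther apart than the cutoff
are forbidden; unmatched detections terminate their track or start a new one.
The assignment maximizes the number of admissible links and, among such
matchings, minimizes the total linked distance — which coincides with plain
nearest-neighbor linkage whenever that is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["CellTrack", "link_frame_pair", "track_cells"]

_BIG = 1e12


@dataclass
class CellTrack:
    """One tracked object: ordered (t, detection_id, (x, y) µm) samples."""

    track_id: int
    samples: list = field(default_factory=list)   # [(t, det_id, (x, y)), ...]

    def add(self, t: int, det_id: int, xy) -> None:
        self.samples.append((t, det_id, (float(xy[0]), float(xy[1]))))

    def __len__(self) -> int:
        return len(self.samples)


def link_frame_pair(points_a: np.ndarray, points_b: np.ndarray,
                    cutoff: float) -> list:
    """Optimal links between two point sets under a distance cutoff.

    Returns a list of (i, j) index pairs: the minimum-total-distance
    matching of maximum cardinality among pairs with d(i, j) <= cutoff.
    Implemented as a padded square assignment problem in which leaving a
    detection unlinked costs slightly more than any admissible link.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    n, m = len(a), len(b)
    if n == 0 or m == 0 or a.size == 0 or b.size == 0:
        return []
    d = cdist(a, b)
    penalty = cutoff * (1.0 + 1e-9)   # cost of a birth/death slot
    cost = np.full((n + m, n + m), _BIG)
    cost[:n, :m] = np.where(d <= cutoff, d, _BIG)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), penalty, _BIG)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), penalty, _BIG)
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    links = [(int(i), int(j)) for i, j in zip(rows, cols)
             if i < n and j < m and d[i, j] <= cutoff]
    return sorted(links)


def track_cells(frames: list, cutoff: float = 2.5) -> list:
    """Link per-frame centroid lists (µm) into :class:`CellTrack` objects.

    ``frames`` is a sequence of arrays/lists of (x, y) centroids in physical
    units.  A detection without an admissible partner in the next frame ends
    its track; unlinked detections in later frames start new tracks.
    """
    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}   # detection index in current frame -> track
    next_id = 0
    for t, pts in enumerate(frames):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) if len(pts) else np.empty((0, 2))
        if t == 0:
            for i, xy in enumerate(pts):
                tr = CellTrack(next_id)
                next_id += 1
                tr.add(t, i, xy)
                tracks.append(tr)
                active[i] = tr
            prev_pts = pts
            continue
        links = link_frame_pair(prev_pts, pts, cutoff)
        linked_prev = {i for i, _ in links}
        linked_curr = {j for _, j in links}
        new_active: dict[int, CellTrack] = {}
        for i, j in links:
            tr = active[i]
            tr.add(t, j, pts[j])
            new_active[j] = tr
        for j, xy in enumerate(pts):
            if j not in linked_curr:
                tr = CellTrack(next_id)
                next_id += 1
                tr.add(t, j, xy)
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
        prev_pts = pts
    return tracks
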