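"""Frame-to-frame association of detections into per-cell trajectories.

Consecutive frames are linked by the globally optimal one-to-one
assignment minimizing total squared displacement, subject to a hard gate
on the per-link displacement. Among gated pairings the tracker first
maximizes the number of links, then minimizes the summed squared
displacement (otherwise the empty pairing would be trivially optimal).
No gap closing and no merge/split handling: a cell that disappears ends
its track; a new detection starts one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

DEFAULT_GATE_RADIUS = 20.0
# direct-distance interval + 1, so every retained track yields >= 1
# persistence window
DEFAULT_MIN_TRACK_LENGTH = 9


@dataclass(frozen=True)
class Track:
    track_id: int
    frames: np.ndarray   # strictly increasing by 1
    xy: np.ndarray       # (len, 2)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    gate_radius: float = DEFAULT_GATE_RADIUS

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(t.track_id, f, x, y)
                for t in self.tracks
                for f, (x, y) in zip(t.frames, t.xy)]
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])


def link_frames(xy_t: np.ndarray, xy_t1: np.ndarray,
                gate_radius: float = DEFAULT_GATE_RADIUS,
                ) -> list[tuple[int, int]]:
    """Optimally pair detections of frame t with those of frame t+1.

    Returns index pairs (i, j) such that detection i of the first frame is
    linked to detection j of the second. Every link has Euclidean
    displacement <= ``gate_radius``; among all such pairings the result
    has maximum cardinality and, among those, minimum total squared
    displacement. Unpaired detections are simply absent from the pairs
    (track ends / track starts).
    """
    if gate_radius <= 0:
        raise ValueError("gate_radius must be > 0")
    a = np.atleast_2d(np.asarray(xy_t, dtype=float))
    b = np.atleast_2d(np.asarray(xy_t1, dtype=float))
    n = 0 if a.size == 0 else a.shape[0]
    m = 0 if b.size == 0 else b.shape[0]
    if n == 0 or m == 0:
        return []
    d2 = cdist(a, b, metric="sqeuclidean")
    feasible = d2 <= gate_radius ** 2
    if not feasible.any():
        return []

    # Padded square assignment: each real detection may link or take its
    # dummy at cost U. U exceeds any feasible total, so cardinality is
    # maximized first; BIG blocks out-of-gate real links.
    g2 = gate_radius ** 2
    U = (n + m) * g2 + 1.0
    BIG = (n + m + 1) * U
    size = n + m
    cost = np.full((size, size), 0.0)
    cost[:n, :m] = np.where(feasible, d2, BIG)
    cost[:n, m:] = BIG
    cost[n:, :m] = BIG
    cost[:n, m:][np.arange(n), np.arange(n)] = U
    cost[n:, :m][np.arange(m), np.arange(m)] = U
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and feasible[i, j]]


def build_tracks(detections: pd.DataFrame,
                 gate_radius: float = DEFAULT_GATE_RADIUS,
                 min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
                 ) -> TrackSet:
    """Chain frame-to-frame links into trajectories.

    ``detections`` needs columns frame, x, y (as produced by
    :func:`spherotrack.detection.detect_stack`). Tracks shorter than
    ``min_track_length`` frames are discarded.
    """
    if min_track_length < 1:
        raise ValueError("min_track_length must be >= 1")
    if len(detections) == 0:
        return TrackSet(tracks=[], gate_radius=gate_radius)
    detections = detections.sort_values("frame", kind="stable")
    frames = detections["frame"].to_numpy(dtype=int)
    xy = detections[["x", "y"]].to_numpy(dtype=float)

    by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        by_frame[int(f)] = np.flatnonzero(frames == f)

    chains: list[list[int]] = []          # detection-row chains
    open_chain_of: dict[int, int] = {}    # detection row -> chain index
    all_frames = sorted(by_frame)
    for fi in all_frames:
        rows_here = by_frame[fi]
        for r in rows_here:
            if r not in open_chain_of:
                chains.append([int(r)])
                open_chain_of[int(r)] = len(chains) - 1
        if fi + 1 not in by_frame:
            continue
        rows_next = by_frame[fi + 1]
        pairs = link_frames(xy[rows_here], xy[rows_next], gate_radius)
        for i, j in pairs:
            r_prev, r_next = int(rows_here[i]), int(rows_next[j])
            ci = open_chain_of.pop(r_prev)
            chains[ci].append(r_next)
            open_chain_of[r_next] = ci

    tracks = []
    tid = 0
    for chain in chains:
        if len(chain) < min_track_length:
            continue
        tracks.append(Track(track_id=tid,
                            frames=frames[chain].copy(),
                            xy=xy[chain].copy()))
        tid += 1
    return TrackSet(tracks=tracks, gate_radius=gate_radius)
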