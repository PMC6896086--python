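"""Directional persistence statistics for single-cell trajectories.

The persistence ratio of a trajectory window is the direct (chord)
distance between the window endpoints divided by the cumulative path
length over the same window. The direct distance uses an 8-frame window;
the cumulative path is summed over chords sampled every 2 frames, a
coarser sampling that avoids over-counting centroid jitter and hence
under-estimating persistence. A ratio near 1 means linear movement; low
ratios mean random migration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Track, TrackSet

DEFAULT_DIRECT_INTERVAL = 8
DEFAULT_CUM_INTERVAL = 2


@dataclass(frozen=True)
class MotilitySummary:
    """Per-track persistence and polar-plot statistics."""

    track_id: int
    persistence_ratio: float      # unitless, in (0, 1]
    mean_direct_distance: float   # px (or µm if calibrated at reporting)
    net_displacement: float       # px, |end - start|
    endpoint_angle: float         # radians, atan2 of end - start
    n_windows: int


def _as_xy(track) -> np.ndarray:
    if isinstance(track, Track):
        return np.asarray(track.xy, dtype=float)
    return np.asarray(track, dtype=float)


def direct_distance(track, interval: int = DEFAULT_DIRECT_INTERVAL) -> np.ndarray:
    """Endpoint (chord) distance of every sliding window of ``interval`` frames.

    Returns one value per window [t, t+interval], stride 1; an empty array
    if the track is shorter than interval+1 positions.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    xy = _as_xy(track)
    if len(xy) < interval + 1:
        return np.empty(0)
    disp = xy[interval:] - xy[:-interval]
    return np.hypot(disp[:, 0], disp[:, 1])


def cumulative_displacement(track,
                            direct_interval: int = DEFAULT_DIRECT_INTERVAL,
                            cum_interval: int = DEFAULT_CUM_INTERVAL) -> np.ndarray:
    """Path length over each direct-distance window, chord-sampled every
    ``cum_interval`` frames.

    For window [t, t+direct_interval], sums the Euclidean distances between
    positions at t, t+cum_interval, t+2*cum_interval, ..., t+direct_interval.
    """
    if cum_interval < 1:
        raise ValueError("cum_interval must be >= 1")
    if direct_interval % cum_interval != 0:
        raise ValueError("direct_interval must be a multiple of cum_interval")
    xy = _as_xy(track)
    if len(xy) < direct_interval + 1:
        return np.empty(0)
    n_win = len(xy) - direct_interval
    out = np.zeros(n_win)
    steps = np.hypot(*(xy[cum_interval:] - xy[:-cum_interval]).T)  # stride-1 chords
    for k in range(0, direct_interval, cum_interval):
        out += steps[k:k + n_win]
    return out


def persistence_ratio(track,
                      direct_interval: int = DEFAULT_DIRECT_INTERVAL,
                      cum_interval: int = DEFAULT_CUM_INTERVAL) -> float:
    """Mean over sliding windows of direct distance / cumulative path.

    Windows with zero cumulative displacement (no motion) are excluded;
    NaN is returned when no valid window remains.
    """
    d = direct_distance(track, direct_interval)
    c = cumulative_displacement(track, direct_interval, cum_interval)
    valid = c > 0
    if not valid.any():
        return float("nan")
    return float(np.mean(d[valid] / c[valid]))


def window_ratios(track, direct_interval: int = DEFAULT_DIRECT_INTERVAL,
                  cum_interval: int = DEFAULT_CUM_INTERVAL) -> np.ndarray:
    """Per-window ratios (for pooled-window aggregation)."""
    d = direct_distance(track, direct_interval)
    c = cumulative_displacement(track, direct_interval, cum_interval)
    valid = c > 0
    return d[valid] / c[valid]


def summarize_track(track: Track,
                    direct_interval: int = DEFAULT_DIRECT_INTERVAL,
                    cum_interval: int = DEFAULT_CUM_INTERVAL,
                    ) -> MotilitySummary | None:
    """Per-track summary, or None when the track yields no valid window."""
    xy = _as_xy(track)
    d = direct_distance(xy, direct_interval)
    c = cumulative_displacement(xy, direct_interval, cum_interval)
    valid = c > 0
    if len(d) == 0 or not valid.any():
        return None
    net = xy[-1] - xy[0]
    return MotilitySummary(
        track_id=track.track_id if isinstance(track, Track) else -1,
        persistence_ratio=float(np.mean(d[valid] / c[valid])),
        mean_direct_distance=float(np.mean(d)),
        net_displacement=float(np.hypot(*net)),
        endpoint_angle=float(math.atan2(net[1], net[0])),
        n_windows=int(valid.sum()),
    )


def summarize(track_set: TrackSet,
              direct_interval: int = DEFAULT_DIRECT_INTERVAL,
              cum_interval: int = DEFAULT_CUM_INTERVAL,
              mode: str = "per_cell") -> tuple[pd.DataFrame, dict]:
    """Summarize every track of a TrackSet.

    ``mode`` controls aggregation: ``"per_cell"`` (one ratio per track,
    the mean over its windows) or ``"pooled"`` (one row per window, for
    condition-level pooling). Returns (summary DataFrame, diagnostics)
    where diagnostics counts tracks excluded as too short or degenerate.
    """
    if mode not in ("per_cell", "pooled"):
        raise ValueError("mode must be 'per_cell' or 'pooled'")
    excluded = {"too_short": 0, "degenerate": 0}
    rows = []
    for tr in track_set.tracks:
        if len(tr) < direct_interval + 1:
            excluded["too_short"] += 1
            continue
        if mode == "per_cell":
            s = summarize_track(tr, direct_interval, cum_interval)
            if s is None:
                excluded["degenerate"] += 1
                continue
            rows.append((s.track_id, s.persistence_ratio,
                         s.mean_direct_distance, s.net_displacement,
                         s.endpoint_angle, s.n_windows))
        else:
            r = window_ratios(tr, direct_interval, cum_interval)
            if r.size == 0:
                excluded["degenerate"] += 1
                continue
            d = direct_distance(tr, direct_interval)
            for w, (ratio, dd) in enumerate(zip(r, d)):
                rows.append((tr.track_id, float(ratio), float(dd),
                             float("nan"), float("nan"), w))
    cols = ["track_id", "persistence_ratio", "mean_direct_distance",
            "net_displacement", "endpoint_angle", "n_windows"]
    return pd.DataFrame(rows, columns=cols), excluded


def polar_coordinates(track_set: TrackSet) -> pd.DataFrame:
    """Origin-aligned polar endpoint of every track.

    Each track is translated so its first position sits at the origin;
    radius is the net displacement |end - start| and angle its atan2
    direction (x rightward, y downward).
    """
    if len(track_set) == 0:
        raise ValueError("track set is empty")
    rows = []
    for tr in track_set.tracks:
        net = tr.xy[-1] - tr.xy[0]
        rows.append((tr.track_id, float(math.atan2(net[1], net[0])),
                     float(np.hypot(*net))))
    return pd.DataFrame(rows, columns=["track_id", "angle", "radius"])


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Classical two-sample Student's t-test (pooled variance, two-sided).

    Returns (t_statistic, two_sided_p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def save_polar_plot(track_set: TrackSet, path: str, *,
                    title: str | None = None) -> None:
    """Write an origin-aligned trajectory polar plot (vector format)."""
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "spherotrack"  # deterministic ids
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(5, 5))
    for tr in track_set.tracks:
        rel = tr.xy - tr.xy[0]
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        r = np.hypot(rel[:, 0], rel[:, 1])
        ax.plot(theta, r, lw=0.8, alpha=0.7)
    if title:
        ax.set_title(title)
    fig.savefig(path, metadata={"Date": None}
                if path.endswith(".svg") else None)
    plt.close(fig)
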