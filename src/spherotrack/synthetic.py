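"""Ground-truthed synthetic data: cell movies, spheroid images, survival cohorts.

Every generator takes an explicit seed and is bit-reproducible; no global
random state is touched. The generators provide known truth for each
downstream stage: persistent-random-walk trajectories for the tracker and
persistence statistics, spheroid core/halo images with exact pixel-count
areas for the dispersal index, and exponential-hazard cohorts for the
survival analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .detection import ImageStack

SATURATION = np.uint16(65535)


# ---------------------------------------------------------------------------
# Persistent random walks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthTracks:
    """Per-cell, per-frame planar positions with the generating parameters.

    ``positions`` has shape (n_cells, n_frames, 2) in (x, y) pixel
    coordinates; the walk model is a persistent random walk whose heading
    receives independent wrapped-normal increments of standard deviation
    ``turn_sd`` each frame, advancing by ``speed`` pixels per frame with
    reflecting arena boundaries.
    """

    positions: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n_cells, n_frames, _ = self.positions.shape
        return pd.DataFrame({
            "cell_id": np.repeat(np.arange(n_cells), n_frames),
            "frame": np.tile(np.arange(n_frames), n_cells),
            "x": self.positions[..., 0].ravel(),
            "y": self.positions[..., 1].ravel(),
        })


def simulate_prw_tracks(n_cells: int, n_frames: int, speed: float,
                        turn_sd: float, arena: tuple[float, float],
                        seed: int,
                        start_positions: np.ndarray | None = None,
                        ) -> GroundTruthTracks:
    """Simulate persistent random walks with reflecting boundaries.

    Heading evolves as theta_{t+1} = theta_t + eta with
    eta ~ Normal(0, turn_sd^2); each frame the position advances by exactly
    ``speed`` pixels along the current heading. Walks that would leave the
    ``arena`` (width, height) are reflected, flipping the corresponding
    heading component.

    Parameters
    ----------
    start_positions : optional (n_cells, 2) array
        Initial (x, y) positions. Defaults to uniform draws inside the
        arena. Useful for placing cells on a well-separated grid.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if turn_sd < 0:
        raise ValueError("turn_sd must be >= 0")
    width, height = float(arena[0]), float(arena[1])
    if width <= 0 or height <= 0:
        raise ValueError("arena dimensions must be positive")

    rng = np.random.default_rng(seed)
    if start_positions is None:
        pos = rng.uniform([0.0, 0.0], [width, height], size=(n_cells, 2))
    else:
        pos = np.array(start_positions, dtype=float)
        if pos.shape != (n_cells, 2):
            raise ValueError("start_positions must have shape (n_cells, 2)")
        if (pos < 0).any() or (pos[:, 0] > width).any() or (pos[:, 1] > height).any():
            raise ValueError("start_positions must lie within the arena")
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_cells)

    out = np.empty((n_cells, n_frames, 2))
    out[:, 0] = pos
    for t in range(1, n_frames):
        if turn_sd > 0:
            theta = theta + rng.normal(0.0, turn_sd, size=n_cells)
        vx = speed * np.cos(theta)
        vy = speed * np.sin(theta)
        nx = out[:, t - 1, 0] + vx
        ny = out[:, t - 1, 1] + vy
        # reflect off the arena walls, updating headings
        lo_x = nx < 0
        hi_x = nx > width
        nx = np.where(lo_x, -nx, nx)
        nx = np.where(hi_x, 2 * width - nx, nx)
        lo_y = ny < 0
        hi_y = ny > height
        ny = np.where(lo_y, -ny, ny)
        ny = np.where(hi_y, 2 * height - ny, ny)
        flip_x = lo_x | hi_x
        flip_y = lo_y | hi_y
        theta = np.where(flip_x, math.pi - theta, theta)
        theta = np.where(flip_y, -theta, theta)
        out[:, t, 0] = nx
        out[:, t, 1] = ny

    params = dict(n_cells=n_cells, n_frames=n_frames, speed=speed,
                  turn_sd=turn_sd, arena=(width, height), seed=seed)
    return GroundTruthTracks(positions=out, params=params)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticMovieSpec:
    """Imaging model for rendering ground-truth tracks into a movie.

    Cells appear as isotropic Gaussian spots of scale ``psf_sigma`` at their
    continuous positions over a uniform ``background_level``; frames receive
    additive Gaussian read noise of ``noise_sd`` and a seeded fraction
    ``hot_pixel_rate`` of saturated single-pixel defects.
    """

    psf_sigma: float = 2.0
    # A saturated hot pixel carries ~65535 units of flux; the default peak
    # keeps a cell's integrated flux (peak * 2*pi*sigma^2) well above that
    # so Gaussian prefiltering leaves cells dominant over point defects.
    peak_intensity: float = 30000.0
    background_level: float = 800.0
    noise_sd: float = 400.0
    hot_pixel_rate: float = 0.0
    frame_shape: tuple[int, int] = (256, 256)  # (height, width)

    def __post_init__(self):
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if not (0 <= self.hot_pixel_rate < 1):
            raise ValueError("hot_pixel_rate must be in [0, 1)")
        if min(self.peak_intensity, self.background_level) < 0 or self.noise_sd < 0:
            raise ValueError("intensities must be non-negative")


def render_movie(tracks: GroundTruthTracks, spec: SyntheticMovieSpec,
                 seed: int) -> ImageStack:
    """Render tracks into a 16-bit grayscale movie under the imaging model."""
    h, w = spec.frame_shape
    pos = tracks.positions
    if (pos[..., 0] < 0).any() or (pos[..., 0] > w - 1).any() \
            or (pos[..., 1] < 0).any() or (pos[..., 1] > h - 1).any():
        raise ValueError("track positions fall outside frame_shape")

    rng = np.random.default_rng(seed)
    half = int(math.ceil(4 * spec.psf_sigma))
    frames = np.empty((tracks.n_frames, h, w), dtype=np.uint16)
    inv2s2 = 1.0 / (2.0 * spec.psf_sigma ** 2)

    for t in range(tracks.n_frames):
        img = np.full((h, w), spec.background_level, dtype=float)
        for c in range(tracks.n_cells):
            x0, y0 = pos[c, t]
            cx, cy = int(round(x0)), int(round(y0))
            x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, w)
            y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, h)
            xs = np.arange(x_lo, x_hi)
            ys = np.arange(y_lo, y_hi)
            gx = np.exp(-((xs - x0) ** 2) * inv2s2)
            gy = np.exp(-((ys - y0) ** 2) * inv2s2)
            img[y_lo:y_hi, x_lo:x_hi] += spec.peak_intensity * np.outer(gy, gx)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0, float(SATURATION))
        frame = img.astype(np.uint16)
        if spec.hot_pixel_rate > 0:
            n_hot = rng.binomial(h * w, spec.hot_pixel_rate)
            idx = rng.choice(h * w, size=n_hot, replace=False)
            frame.ravel()[idx] = SATURATION
        frames[t] = frame

    return ImageStack(frames=frames)


# ---------------------------------------------------------------------------
# Spheroid image pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpheroid:
    """A spheroid core plus a halo of dispersed cells, with exact truth areas.

    At t0 only the core disk (radius ``core_radius_t0``) is present; at 24 h
    the core has radius ``core_radius_t24`` and ``n_dispersed`` non-
    overlapping blob cells of radius ``blob_radius`` lie in the annulus
    between the core and ``halo_radius``.
    """

    core_radius_t0: float = 20.0
    core_radius_t24: float = 18.0
    n_dispersed: int = 12
    halo_radius: float = 60.0
    blob_radius: float = 3.0
    # Minimum gap between the core edge and any blob edge; must exceed
    # twice the dispersal module's closing radius or closing would fuse
    # near blobs into the core.
    clearance: float = 16.0
    foreground: int = 200
    background: int = 10

    def __post_init__(self):
        if self.core_radius_t24 < 0:
            raise ValueError("core_radius_t24 must be >= 0")
        if self.halo_radius < max(self.core_radius_t0, self.core_radius_t24):
            raise ValueError("halo_radius must be >= the core radius")


def _disk_mask(shape: tuple[int, int], cx: float, cy: float,
               radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def make_spheroid_pair(spec: SyntheticSpheroid, seed: int):
    """Render (image_t0, image_t24) and return them with exact truth areas.

    Returns ``(image_t0, image_t24, truth)`` where ``truth`` is a
    :class:`~spherotrack.dispersal.SpheroidMeasurement` whose areas are the
    exact pixel counts of the rendered binary masks.
    """
    from .dispersal import SpheroidMeasurement  # avoid circular import

    rng = np.random.default_rng(seed)
    margin = 2 * spec.blob_radius + 4
    side = int(math.ceil(2 * (spec.halo_radius + margin)))
    shape = (side, side)
    cx = cy = side / 2.0

    core_t0 = _disk_mask(shape, cx, cy, spec.core_radius_t0)
    core_t24 = _disk_mask(shape, cx, cy, spec.core_radius_t24)

    # dispersed blobs: outside the core, inside the halo, non-overlapping
    blobs = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float]] = []
    placed = 0
    attempts = 0
    r_lo = spec.core_radius_t24 + spec.blob_radius + spec.clearance
    r_hi = spec.halo_radius
    if spec.n_dispersed > 0 and r_hi <= r_lo:
        raise ValueError("halo_radius leaves no room for dispersed cells")
    while placed < spec.n_dispersed:
        attempts += 1
        if attempts > 10000 * max(spec.n_dispersed, 1):
            raise RuntimeError("could not place non-overlapping dispersed cells")
        r = rng.uniform(r_lo, r_hi)
        phi = rng.uniform(0, 2 * math.pi)
        bx, by = cx + r * math.cos(phi), cy + r * math.sin(phi)
        if any((bx - ox) ** 2 + (by - oy) ** 2 < (2 * spec.blob_radius + 2) ** 2
               for ox, oy in centers):
            continue
        centers.append((bx, by))
        blobs |= _disk_mask(shape, bx, by, spec.blob_radius)
        placed += 1

    total_t24 = core_t24 | blobs

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full(shape, spec.background, dtype=np.uint16)
        img[mask] = spec.foreground
        return img

    truth = SpheroidMeasurement(
        sphere_area_t0=int(core_t0.sum()),
        sphere_area_t24=int(core_t24.sum()),
        total_area_t24=int(total_t24.sum()),
    )
    return render(core_t0), render(total_t24), truth


def make_dispersal_stack(n_frames: int, core_radius: float,
                         halo_growth: float, seed: int,
                         n_cells_per_frame: int = 3,
                         blob_radius: float = 3.0,
                         foreground: int = 200, background: int = 10):
    """Growing-halo stack for the relative dispersal time course.

    Frame 0 holds the bare core; each later frame adds
    ``n_cells_per_frame`` blobs at radii growing by ``halo_growth`` px per
    frame. Returns ``(ImageStack, truth_areas)`` with truth footprint pixel
    counts per frame.
    """
    rng = np.random.default_rng(seed)
    max_r = core_radius + halo_growth * n_frames + 3 * blob_radius + 6
    side = int(math.ceil(2 * max_r))
    shape = (side, side)
    cx = cy = side / 2.0
    mask = _disk_mask(shape, cx, cy, core_radius)
    frames = np.empty((n_frames, side, side), dtype=np.uint16)
    truth = np.empty(n_frames, dtype=int)
    for t in range(n_frames):
        if t > 0:
            for _ in range(n_cells_per_frame):
                r = core_radius + blob_radius + 2 + rng.uniform(0, halo_growth * t)
                phi = rng.uniform(0, 2 * math.pi)
                mask = mask | _disk_mask(shape, cx + r * math.cos(phi),
                                         cy + r * math.sin(phi), blob_radius)
        img = np.full(shape, background, dtype=np.uint16)
        img[mask] = foreground
        frames[t] = img
        truth[t] = int(mask.sum())
    return ImageStack(frames=frames), truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Exponential-hazard cohort with a log-linear expression effect.

    Each subject carries a raw expression value whose standardised log2
    score z modulates the event hazard as
    ``hazard = baseline_hazard * exp(coefficient * z)``; censoring times are
    drawn independently from a Uniform(0, u) with u calibrated so that the
    expected censored fraction at the baseline hazard equals
    ``censoring_rate``.
    """

    n_subjects: int = 200
    coefficient: float = 0.0       # log-hazard per expression SD
    baseline_hazard: float = 1.0 / 500.0   # events per day
    censoring_rate: float = 0.3
    expression_log2_mean: float = 6.0
    expression_log2_sd: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


def _uniform_censor_bound(lam: float, target_rate: float) -> float:
    """Solve for u such that P(C < T) = target_rate with T~Exp(lam), C~U(0,u).

    P(censored) = P(C < T) = 1 - (1 - exp(-lam*u)) / (lam*u).
    """
    def f(u):
        x = lam * u
        return (1.0 - math.exp(-x)) / x - target_rate

    # f decreases from 1 (u->0) toward 0 (u->inf)
    hi = 1.0 / lam
    while f(hi) > 0:
        hi *= 2
    return brentq(f, 1e-12 / lam, hi)


def simulate_cohort(spec: SyntheticCohortSpec, seed: int) -> pd.DataFrame:
    """Draw a survival cohort: columns subject_id, expression, time, event.

    ``time`` is min(event time, censor time) in days, ``event`` is 1 when
    the event was observed. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    z = rng.normal(0.0, 1.0, size=n)
    raw = np.exp2(spec.expression_log2_mean + spec.expression_log2_sd * z)
    hazard = spec.baseline_hazard * np.exp(spec.coefficient * z)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        u = _uniform_censor_bound(spec.baseline_hazard, spec.censoring_rate)
        t_cens = rng.uniform(0.0, u, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    time = np.maximum(time, np.finfo(float).tiny)  # keep times strictly > 0
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "expression": raw,
        "time": time,
        "event": event,
    })
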