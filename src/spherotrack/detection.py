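"""Per-frame cell detection: Gaussian denoising, threshold segmentation,
and intensity-weighted centroid extraction.

Coordinate convention, fixed project-wide: 0-based pixel-center
coordinates, x rightward (columns), y downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

DEFAULT_SIGMA = 3.0
DEFAULT_MIN_AREA = 4


@dataclass(frozen=True)
class ImageStack:
    """Ordered grayscale frames with optional physical calibration.

    ``pixel_size`` is in µm/px and ``frame_interval`` in minutes/frame;
    both are metadata only — all image math stays in pixels and frames.
    """

    frames: np.ndarray            # (n_frames, h, w)
    pixel_size: float | None = None
    frame_interval: float | None = None

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, h, w) array with >= 1 frame")
        if not np.isfinite(np.asarray(f, dtype=float)).all():
            raise ValueError("frame intensities must be finite")
        if (np.asarray(f, dtype=float) < 0).any():
            raise ValueError("frame intensities must be non-negative")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame."""

    frame_index: int
    x: float
    y: float
    area: int
    total_intensity: float

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


def remove_point_defects(frame: np.ndarray,
                         saturation: float = 65535) -> np.ndarray:
    """Replace saturated pixels (camera point defects) by the 3x3 median.

    Hot pixels read out at full scale regardless of the scene; repairing
    them before smoothing keeps clustered defects from surviving the
    Gaussian filter as spurious blobs.
    """
    frame = np.asarray(frame, dtype=float)
    sat = frame >= saturation
    if sat.any():
        med = ndi.median_filter(frame, size=3, mode="mirror")
        frame = frame.copy()
        frame[sat] = med[sat]
    return frame


def denoise(frame: np.ndarray, sigma: float = DEFAULT_SIGMA, *,
            allow_small_sigma: bool = False) -> np.ndarray:
    """Linear Gaussian smoothing to suppress single-pixel point defects.

    The default enforces a lower bound of 3 px on the Gaussian sigma, the
    scale needed to flatten isolated hot pixels below the segmentation
    threshold; pass ``allow_small_sigma=True`` to override. The kernel is
    truncated at 4 sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if sigma < 3 and not allow_small_sigma:
        raise ValueError("sigma < 3 px defeats point-defect removal; "
                         "pass allow_small_sigma=True to override")
    # mirror padding: unlike nearest/reflect it does not duplicate the
    # border pixel, so an edge hot pixel is not amplified by the padding
    return ndi.gaussian_filter(np.asarray(frame, dtype=float), sigma,
                               mode="mirror", truncate=4.0)


def segment(frame: np.ndarray, threshold: float | str = "otsu",
            min_area: int = DEFAULT_MIN_AREA, *,
            blank_guard_z: float = 3.0) -> np.ndarray:
    """Threshold the (denoised) frame and label connected components.

    ``threshold`` is either an absolute intensity or ``"otsu"``. Components
    smaller than ``min_area`` pixels are discarded. With Otsu, a guard
    rejects blank frames: if the foreground/background mean separation is
    below ``blank_guard_z`` background standard deviations the frame is
    treated as empty (all labels 0) rather than splitting pure noise.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    frame = np.asarray(frame, dtype=float)
    if threshold == "otsu":
        if np.ptp(frame) == 0:
            return np.zeros(frame.shape, dtype=np.int32)
        t = threshold_otsu(frame)
        fg = frame > t
        if not fg.any() or fg.all():
            return np.zeros(frame.shape, dtype=np.int32)
        bg_sd = frame[~fg].std()
        sep = frame[fg].mean() - frame[~fg].mean()
        if bg_sd > 0 and sep < blank_guard_z * bg_sd:
            return np.zeros(frame.shape, dtype=np.int32)
    else:
        t = float(threshold)
        fg = frame > t
    labels = _cc_label(fg, connectivity=2)
    if min_area > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = _cc_label(labels > 0, connectivity=2)
    return labels.astype(np.int32)


def centroids(labeled_mask: np.ndarray, intensity_frame: np.ndarray,
              frame_index: int = 0) -> list[Detection]:
    """Intensity-weighted centroid of each labeled component.

    The centroid of a label is the mean pixel coordinate over its pixels
    weighted by the intensity values of ``intensity_frame``.
    """
    labeled_mask = np.asarray(labeled_mask)
    intensity_frame = np.asarray(intensity_frame, dtype=float)
    if labeled_mask.shape != intensity_frame.shape:
        raise ValueError("mask and frame must have the same shape")
    ids = np.arange(1, labeled_mask.max() + 1)
    if ids.size == 0:
        return []
    coms = ndi.center_of_mass(intensity_frame, labeled_mask, ids)
    sums = ndi.sum_labels(intensity_frame, labeled_mask, ids)
    areas = ndi.sum_labels(np.ones_like(labeled_mask), labeled_mask, ids)
    return [Detection(frame_index=frame_index, x=float(cy_cx[1]),
                      y=float(cy_cx[0]), area=int(a), total_intensity=float(s))
            for cy_cx, s, a in zip(coms, sums, areas)]


def detect_stack(stack: ImageStack, sigma: float = DEFAULT_SIGMA,
                 threshold: float | str = "otsu",
                 min_area: int = DEFAULT_MIN_AREA, *,
                 allow_small_sigma: bool = False,
                 saturation: float | None = 65535) -> pd.DataFrame:
    """Denoise, segment, and extract centroids for every frame.

    Saturated point defects are median-repaired before Gaussian smoothing
    (pass ``saturation=None`` to disable). Returns a DataFrame with
    columns frame, x, y, area, total_intensity.
    """
    rows = []
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        if saturation is not None:
            frame = remove_point_defects(frame, saturation)
        smooth = denoise(frame, sigma,
                         allow_small_sigma=allow_small_sigma)
        labels = segment(smooth, threshold, min_area)
        for det in centroids(labels, smooth, frame_index=t):
            rows.append((det.frame_index, det.x, det.y, det.area,
                         det.total_intensity))
    return pd.DataFrame(rows, columns=["frame", "x", "y", "area",
                                       "total_intensity"])
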