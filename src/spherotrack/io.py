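"""Reading and writing the pipeline's file formats.

Images travel as multi-page TIFF (16-bit grayscale) or numbered PNG
sequences; all tabular data are headered CSV files.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detection import ImageStack
from .tracking import Track, TrackSet

DETECTION_COLUMNS = ["frame", "x", "y", "area", "total_intensity"]
TRACK_COLUMNS = ["track_id", "frame", "x", "y"]


def read_stack(path: str, pixel_size: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read an image stack from a TIFF file or a glob of numbered images."""
    if os.path.isfile(path):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        files = sorted(glob.glob(path))
        if not files:
            raise FileNotFoundError(f"no images match {path!r}")
        frames = np.stack([iio.imread(f) for f in files])
    return ImageStack(frames=frames, pixel_size=pixel_size,
                      frame_interval=frame_interval)


def write_stack(path: str, stack: ImageStack) -> None:
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.uint16))


def read_image(path: str) -> np.ndarray:
    img = iio.imread(path) if not path.lower().endswith((".tif", ".tiff")) \
        else tifffile.imread(path)
    if img.ndim == 3:  # collapse RGB to gray
        img = img.mean(axis=-1)
    return np.asarray(img)


def write_detections(path: str, detections: pd.DataFrame) -> None:
    detections.to_csv(path, index=False, columns=DETECTION_COLUMNS)


def read_detections(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    return df


def write_tracks(path: str, track_set: TrackSet) -> None:
    track_set.to_dataframe().to_csv(path, index=False)


def read_tracks(path: str, gate_radius: float = float("nan")) -> TrackSet:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(Track(track_id=int(tid),
                            frames=sub["frame"].to_numpy(dtype=int),
                            xy=sub[["x", "y"]].to_numpy(dtype=float)))
    return TrackSet(tracks=tracks, gate_radius=gate_radius)


def write_table(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
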