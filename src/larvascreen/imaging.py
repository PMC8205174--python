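"""Frame-sequence and tabular I/O.

Defines the on-disk contracts the rest of the toolkit consumes: grayscale
frame stacks (multi-page TIFF or directories of single-frame images) and the
per-well movement-record CSV. All times are seconds relative to compound
addition, so baseline acquisitions carry negative ``acquired_at_s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "AcquisitionSeries",
    "MovementRecord",
    "load_frame_stack",
    "save_frame_stack",
    "save_movement_table",
    "load_movement_table",
    "natural_sort_key",
]

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}

#: CSV column order for movement-record tables.
MOVEMENT_COLUMNS = [
    "plate_id",
    "well",
    "timepoint_s",
    "raw_index",
    "normalized_index",
    "replicate",
]


@dataclass
class FrameStack:
    """A timed sequence of equal-size grayscale frames for one plate/timepoint.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative intensities (8/16-bit range).
    frame_interval_ms
        Nominal interval between frames; the reference acquisition protocol
        uses 10 ms.
    acquired_at_s
        Acquisition time relative to compound addition (negative = baseline).
    """

    frames: np.ndarray
    frame_interval_ms: float = 10.0
    acquired_at_s: float = 0.0
    plate_id: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a T x H x W array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("frame stack contains zero frames")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frame intensities must be non-negative")
        if not self.frame_interval_ms > 0:
            raise ValueError("frame_interval_ms must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """Return a copy holding ``frames`` with all metadata preserved."""
        return replace(self, frames=frames)


@dataclass
class AcquisitionSeries:
    """Baseline plus post-compound frame stacks for one plate.

    ``baseline`` stacks are recorded immediately before compound addition
    (``acquired_at_s`` <= 0); ``post`` stacks are sorted ascending in time.
    """

    baseline: list[FrameStack]
    post: list[FrameStack] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.baseline:
            raise ValueError("at least one baseline stack is required")
        self.post = sorted(self.post, key=lambda s: s.acquired_at_s)
        for stack in self.post:
            if stack.acquired_at_s <= 0:
                raise ValueError(
                    "post stacks must have acquired_at_s > 0 "
                    f"(got {stack.acquired_at_s})"
                )


@dataclass
class MovementRecord:
    """Per-well movement index at one timepoint.

    ``raw_index`` counts super-threshold pixels in the well; ``normalized_index``
    is raw divided by the same well's pre-compound baseline. A NaN
    ``normalized_index`` flags an undefined value (zero baseline) which is
    excluded from downstream fits.
    """

    well: str
    timepoint_s: float
    raw_index: int
    normalized_index: float
    replicate: int = 1
    plate_id: str = ""

    @property
    def is_defined(self) -> bool:
        return bool(np.isfinite(self.normalized_index))


def natural_sort_key(name: str) -> tuple:
    """Sort key that orders embedded integers numerically (frame_2 < frame_10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        # unweighted channel mean; alpha dropped
        return frame[..., :3].mean(axis=-1)
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as grayscale")


def _load_directory(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES),
        key=lambda p: natural_sort_key(p.name),
    )
    if not files:
        raise ValueError(f"no frame images (*.tif, *.tiff, *.png) found in {path}")
    frames = []
    for f in files:
        img = _to_grayscale(iio.imread(f))
        if frames and img.shape != frames[0].shape:
            raise ValueError(
                f"mixed frame sizes: {f.name} is {img.shape}, "
                f"expected {frames[0].shape}"
            )
        frames.append(img)
    return np.stack(frames)


def _load_multipage(path: Path) -> np.ndarray:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:  # pages with color channels
        data = np.stack([_to_grayscale(page) for page in data])
    if data.ndim != 3:
        raise ValueError(f"cannot interpret {path} as a frame stack: shape {data.shape}")
    return data


def load_frame_stack(
    path: str | Path,
    frame_interval_ms: float = 10.0,
    acquired_at_s: float = 0.0,
    plate_id: str = "",
    timepoint_label: str = "",
) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of images.

    Directory frames are ordered by natural (numeric-aware) filename sort, so
    differing zero-padding cannot shuffle them. Color frames are reduced to
    grayscale by unweighted channel mean.
    """
    path = Path(path)
    if path.is_dir():
        frames = _load_directory(path)
    elif path.exists():
        frames = _load_multipage(path)
    else:
        raise FileNotFoundError(path)
    return FrameStack(
        frames=frames,
        frame_interval_ms=frame_interval_ms,
        acquired_at_s=acquired_at_s,
        plate_id=plate_id or path.stem,
        timepoint_label=timepoint_label,
    )


def save_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames))
    return path


def save_movement_table(
    records: Sequence[MovementRecord], path: str | Path
) -> Path:
    """Write movement records as a CSV re-loadable to full precision."""
    if not records:
        raise ValueError("no movement records to write")
    path = Path(path)
    frame = pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in records],
            "well": [r.well for r in records],
            "timepoint_s": [r.timepoint_s for r in records],
            "raw_index": [r.raw_index for r in records],
            "normalized_index": [r.normalized_index for r in records],
            "replicate": [r.replicate for r in records],
        }
    )
    # default float formatting is shortest-repr, which round-trips exactly
    frame.to_csv(path, index=False)
    return path


def load_movement_table(path: str | Path) -> list[MovementRecord]:
    """Read a movement-record CSV written by :func:`save_movement_table`."""
    frame = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            MovementRecord(
                well=str(row.well),
                timepoint_s=float(row.timepoint_s),
                raw_index=int(row.raw_index),
                normalized_index=float(row.normalized_index),
                replicate=int(row.replicate),
                plate_id="" if pd.isna(row.plate_id) else str(row.plate_id),
            )
        )
    return records
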