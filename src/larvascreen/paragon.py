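"""Pixel-variance movement quantification (the Paragon algorithm).

The movement index of a well is the number of its pixels whose temporal
intensity variance, computed over a small subsample of frames (by default
frames 1, 11 and 21 of a 30-frame, 10 ms-interval sequence), strictly exceeds
the image-wide mean variance by three standard deviations. Indices measured
after compound addition are normalized by the same well's pre-compound
baseline, and replicates are aggregated by median.

The threshold is scale-free: replacing every intensity P by a*P + b (a > 0)
scales all variances by a^2 and the mean + 3*sigma cutoff identically, so the
binary motion map — and hence every movement index — is unchanged. For the
same reason population versus sample variance makes no difference to the map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .imaging import AcquisitionSeries, FrameStack, MovementRecord
from .plate import PlateMap

__all__ = [
    "VarianceMap",
    "BinaryMotionMap",
    "ParagonParams",
    "select_frames",
    "temporal_variance",
    "threshold_motion",
    "movement_index",
    "normalize_index",
    "aggregate_replicates",
    "measure_stack",
    "measure_plate",
    "DEFAULT_FRAME_POSITIONS",
]

#: 1-based frame positions sampled from each 30-frame sequence.
DEFAULT_FRAME_POSITIONS: tuple[int, ...] = (1, 11, 21)


@dataclass
class VarianceMap:
    """Per-pixel temporal variance of a frame stack (H x W, non-negative)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("variance map must be 2-D")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("variance map must be non-negative")


@dataclass
class BinaryMotionMap:
    """H x W indicator of super-threshold-variance ('moving') pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary motion map entries must be 0 or 1")


@dataclass
class ParagonParams:
    """Tunables of the movement-index pipeline.

    frame_positions are 1-based, mirroring the "frames 1, 11 and 21"
    convention; threshold_scope is "global" (one mean/std over the whole
    image, the default) or "per-well".
    """

    frame_positions: tuple[int, ...] = DEFAULT_FRAME_POSITIONS
    sigma_mult: float = 3.0
    threshold_scope: str = "global"

    def __post_init__(self) -> None:
        if self.threshold_scope not in ("global", "per-well"):
            raise ValueError("threshold_scope must be 'global' or 'per-well'")


def select_frames(
    stack: FrameStack, positions: Sequence[int] = DEFAULT_FRAME_POSITIONS
) -> FrameStack:
    """Return the sub-stack at the given 1-based frame positions, in order."""
    bad = [p for p in positions if p < 1 or p > stack.n_frames]
    if bad:
        raise IndexError(
            f"frame position(s) {bad} out of range for a {stack.n_frames}-frame stack"
        )
    idx = [p - 1 for p in positions]
    return stack.with_frames(stack.frames[idx])


def temporal_variance(stack: FrameStack) -> VarianceMap:
    """Per-pixel population variance (divisor T) across the stack's frames."""
    if stack.n_frames < 2:
        raise ValueError("temporal variance needs at least 2 frames")
    values = np.var(np.asarray(stack.frames, dtype=float), axis=0, ddof=0)
    return VarianceMap(values)


def threshold_motion(
    vmap: VarianceMap | np.ndarray, sigma_mult: float = 3.0
) -> BinaryMotionMap:
    """Mark pixels whose variance strictly exceeds mean + sigma_mult * std.

    Mean and (population) std are taken over all pixels of the map. On a
    uniform map std is zero and nothing can strictly exceed its own mean, so
    the result is all zeros.
    """
    if sigma_mult <= 0:
        raise ValueError("sigma_mult must be positive")
    values = np.asarray(getattr(vmap, "values", vmap), dtype=float)
    if values.size == 0:
        raise ValueError("empty variance map")
    cutoff = values.mean() + sigma_mult * values.std(ddof=0)
    return BinaryMotionMap((values > cutoff).astype(np.uint8))


def movement_index(bmap: BinaryMotionMap | np.ndarray, region: np.ndarray) -> int:
    """Count 1-pixels of the motion map inside a boolean region mask."""
    values = np.asarray(getattr(bmap, "values", bmap))
    region = np.asarray(region, dtype=bool)
    if region.shape != values.shape:
        raise ValueError(
            f"region shape {region.shape} does not match map shape {values.shape}"
        )
    return int(values[region].sum())


def normalize_index(post_index: float, baseline_index: float) -> float:
    """post / baseline; a zero baseline flags the value undefined (NaN)."""
    if baseline_index < 0:
        raise ValueError("baseline index must be non-negative")
    if baseline_index == 0:
        return math.nan
    return post_index / baseline_index


def aggregate_replicates(values: Iterable[float]) -> float:
    """Median of defined replicate values (NaN-flagged entries are dropped)."""
    kept = [v for v in values if not math.isnan(v)]
    if not kept:
        raise ValueError("no defined replicate values to aggregate")
    return float(np.median(kept))


def measure_stack(
    stack: FrameStack, plate: PlateMap, params: ParagonParams | None = None
) -> dict[str, int]:
    """Raw movement index per well for a single frame stack."""
    params = params or ParagonParams()
    sub = select_frames(stack, params.frame_positions)
    vmap = temporal_variance(sub)
    if params.threshold_scope == "global":
        bmap = threshold_motion(vmap, params.sigma_mult)
        return {w: movement_index(bmap, plate.regions[w]) for w in plate.wells}
    indices = {}
    for w in plate.wells:
        region = plate.regions[w]
        well_values = vmap.values[region]
        cutoff = well_values.mean() + params.sigma_mult * well_values.std(ddof=0)
        indices[w] = int((well_values > cutoff).sum())
    return indices


def _median_indices(
    stacks: Sequence[FrameStack], plate: PlateMap, params: ParagonParams
) -> dict[str, float]:
    """Per-well median raw index across several sequences of one timepoint."""
    per_stack = [measure_stack(s, plate, params) for s in stacks]
    return {
        w: float(np.median([idx[w] for idx in per_stack])) for w in plate.wells
    }


def measure_plate(
    series: AcquisitionSeries,
    plate: PlateMap,
    params: ParagonParams | None = None,
    replicate: int = 1,
) -> list[MovementRecord]:
    """Run the full pipeline over one acquisition series.

    Per-well baseline = median raw index across the baseline stacks; post
    stacks are grouped by acquisition time (several image sequences per
    timepoint are aggregated by median) and each timepoint's index is
    normalized by the well's baseline. Returns one record per well per post
    timepoint.
    """
    params = params or ParagonParams()
    shape = series.baseline[0].frame_shape
    for stack in list(series.baseline) + list(series.post):
        if stack.frame_shape != shape:
            raise ValueError("all stacks in a series must share frame dimensions")
    if shape[0] < plate.bbox.bottom or shape[1] < plate.bbox.right:
        raise ValueError(
            f"plate bbox {plate.bbox} exceeds frame dimensions {shape}"
        )

    baseline = _median_indices(series.baseline, plate, params)

    by_time: dict[float, list[FrameStack]] = {}
    for stack in series.post:
        by_time.setdefault(stack.acquired_at_s, []).append(stack)

    plate_id = series.baseline[0].plate_id
    records: list[MovementRecord] = []
    for t in sorted(by_time):
        raw = _median_indices(by_time[t], plate, params)
        for w in plate.wells:
            records.append(
                MovementRecord(
                    well=w,
                    timepoint_s=float(t),
                    raw_index=int(round(raw[w])),
                    normalized_index=normalize_index(raw[w], baseline[w]),
                    replicate=replicate,
                    plate_id=plate_id,
                )
            )
    return records
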