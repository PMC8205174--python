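"""Online per-pixel mean/variance over a frame feed (the smartphone pathway).

A low-power camera cannot buffer whole image sequences, so the per-pixel mean
and variance are maintained incrementally, one frame at a time:

    M_n = M_{n-1} + (P - M_{n-1}) / n
    V_n = ((n-1) * V_{n-1} + (P - M_{n-1}) * (P - M_n)) / n

with M_1 = P and V_1 = 0. This is the population-variance (divisor n) form of
Welford's algorithm: after any number of frames V equals the two-pass
population variance of the frames seen so far, to rounding error.

Measurement runs in cycles: the accumulator is reset, a fixed number of
frames (default 60, ~2 s at 30 fps on 320x240 frames) is accumulated, and the
(mean, variance) matrices are exported; cycles repeat on a fixed period
(default 10 s). Per-well motility traces are the mean of the variance matrix
over each well's pixels at each cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "StreamingAccumulator",
    "CycleExport",
    "VarianceTimeSeries",
    "stream_update",
    "measure_cycle",
    "well_series",
]


@dataclass
class StreamingAccumulator:
    """Running per-pixel mean (M_n) and population variance (V_n) over n frames."""

    mean: np.ndarray | None = None
    var: np.ndarray | None = None
    n: int = 0

    def reset(self) -> None:
        self.mean = None
        self.var = None
        self.n = 0


@dataclass(frozen=True)
class CycleExport:
    """One per-cycle dump of the (mean, variance) matrices at time ``t_s``."""

    mean: np.ndarray
    var: np.ndarray
    t_s: float
    n_frames: int


@dataclass
class VarianceTimeSeries:
    """Mean-of-variance trace for one well across measurement cycles."""

    well: str
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times_s.size > 1 and not (np.diff(self.times_s) > 0).all():
            raise ValueError("times must be strictly ascending")
        if self.values.size and self.values.min() < 0:
            raise ValueError("variance values must be non-negative")

    def __len__(self) -> int:
        return int(self.times_s.size)


def stream_update(acc: StreamingAccumulator, frame: np.ndarray) -> StreamingAccumulator:
    """Fold one frame into the accumulator (in place; also returned).

    The first frame initializes M = P, V = 0; later frames apply the
    mean/variance recurrences elementwise.
    """
    frame = np.asarray(frame, dtype=float)
    if acc.n == 0:
        acc.mean = frame.copy()
        acc.var = np.zeros_like(frame)
        acc.n = 1
        return acc
    if frame.shape != acc.mean.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match accumulator {acc.mean.shape}"
        )
    n = acc.n + 1
    prev_mean = acc.mean
    new_mean = prev_mean + (frame - prev_mean) / n
    acc.var = ((n - 1) * acc.var + (frame - prev_mean) * (frame - new_mean)) / n
    acc.mean = new_mean
    acc.n = n
    return acc


def measure_cycle(
    feed: Iterable[np.ndarray],
    frames_per_cycle: int = 60,
    cycle_period_s: float = 10.0,
    frame_interval_s: float = 1.0 / 30.0,
    start_time_s: float = 0.0,
) -> list[CycleExport]:
    """Consume a frame feed in reset-per-cycle measurement cycles.

    Each cycle accumulates ``frames_per_cycle`` frames into a fresh
    accumulator and exports (mean, var) stamped at the cycle's capture
    midpoint; cycles start every ``cycle_period_s``. A feed exhausted
    mid-cycle discards the partial cycle with a warning.
    """
    if frames_per_cycle < 2:
        raise ValueError("frames_per_cycle must be >= 2")
    if cycle_period_s <= 0 or frame_interval_s <= 0:
        raise ValueError("periods must be positive")
    capture_s = frames_per_cycle * frame_interval_s
    exports: list[CycleExport] = []
    acc = StreamingAccumulator()
    it: Iterator[np.ndarray] = iter(feed)
    cycle = 0
    while True:
        acc.reset()
        got = 0
        for _ in range(frames_per_cycle):
            try:
                frame = next(it)
            except StopIteration:
                break
            stream_update(acc, frame)
            got += 1
        if got == frames_per_cycle:
            exports.append(
                CycleExport(
                    mean=acc.mean.copy(),
                    var=acc.var.copy(),
                    t_s=start_time_s + cycle * cycle_period_s + capture_s / 2.0,
                    n_frames=got,
                )
            )
            cycle += 1
        else:
            if got > 0:
                warnings.warn(
                    f"feed exhausted mid-cycle: discarding partial cycle of {got} frames"
                )
            break
    return exports


def well_series(
    exports: Sequence[CycleExport],
    well_masks: Mapping[str, np.ndarray],
) -> list[VarianceTimeSeries]:
    """Per-well mean-of-variance traces across cycle exports."""
    series = []
    for well, mask in well_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"well {well}: empty mask")
        times, values = [], []
        for export in exports:
            if mask.shape != export.var.shape:
                raise ValueError(
                    f"well {well}: mask shape {mask.shape} does not match "
                    f"variance grid {export.var.shape}"
                )
            times.append(export.t_s)
            values.append(float(export.var[mask].mean()))
        series.append(
            VarianceTimeSeries(well=well, times_s=np.array(times), values=np.array(values))
        )
    return series
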