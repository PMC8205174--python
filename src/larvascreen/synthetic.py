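"""Seeded synthetic plate videos, dose tables, and decay traces.

Every generator is a pure function of its parameters and seed, and returns
the ground truth alongside the artifact, so the whole toolkit is testable
without real recordings.

The plate simulator emulates the features of larval-motility videos that the
measurement pipeline keys on: each well holds a handful (default 5-10) of
small bright larvae on a dark background that drift slowly (Gaussian steps),
occasionally jump (Poisson events with a larger displacement), and are
reflected at the well walls. A compound dose scales the whole motion process
— both the drift step SD and the jump rate — by the same Hill factor
``predict_sigmoid(log10 C, I, H)`` later recovered by the dose-response fit,
which closes the loop and makes pIC50 recovery well-posed. Gaussian sensor
noise is added before 8-bit quantization. It does not attempt photorealism:
no hydrodynamics, no instar size variation, no death-versus-paralysis
distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .decay import decay_model
from .dose import DoseResponsePoint, predict_sigmoid
from .imaging import AcquisitionSeries, FrameStack
from .plate import PlateMap, Rect, build_grid
from .streaming import VarianceTimeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_plate",
    "simulate_series",
    "simulate_dose_table",
    "simulate_decay_series",
]


@dataclass
class SimulationConfig:
    """Plate-video simulation parameters.

    Geometry follows the 96-well standard (8 x 12) at 80 px per well — a
    640 x 960 px plate image, matching the ~80 px/well optics of plate-camera
    rigs, where a first-instar larva (~1.3 mm) spans ~16 x 3 px and the 5-10
    larvae cover ~5% of each well. Acquisition defaults mirror the reference
    protocol: 30 frames per sequence at 10 ms intervals. Drift steps are of
    order the larva width per sampled-frame gap (slow filter-feeding motion);
    jumps displace a larva by roughly its own length.
    :meth:`reduced` gives a quarter-resolution variant for bulk simulation.
    """

    rows: int = 8
    cols: int = 12
    well_px: int = 80
    larvae_per_well: tuple[int, int] = (5, 10)
    motility: float = 0.3  # drift step SD, px/frame
    jump_rate: float = 0.01  # jump events per frame per larva
    jump_scale: float = 20.0  # jump displacement, px
    larva_length_px: float = 16.0
    larva_width_px: float = 3.0
    background: float = 30.0  # intensity levels (8-bit scale)
    foreground: float = 200.0
    noise_sd: float = 2.0  # sensor noise SD, intensity levels
    frames: int = 30
    frame_interval_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.larvae_per_well
        if lo < 1 or hi < lo:
            raise ValueError("larvae_per_well must be a (min, max) range with min >= 1")
        for name in ("motility", "jump_rate", "jump_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        """Quarter-resolution variant (20 px wells, a 96-well plate fits in
        160 x 240 px) preserving the default larva density and the ratio of
        drift step to larva size; used where many plates must be rendered."""
        base = dict(
            well_px=20,
            larva_length_px=5.0,
            larva_width_px=1.0,
            motility=0.075,
            jump_scale=6.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.rows * self.well_px, self.cols * self.well_px

    def plate_map(self) -> PlateMap:
        h, w = self.frame_shape
        return build_grid(Rect(0, 0, w, h), rows=self.rows, cols=self.cols)


@dataclass
class GroundTruth:
    """Planted parameters recoverable alongside every generated artifact."""

    params: dict = field(default_factory=dict)
    per_well: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# plate videos

def _paint_ellipse(
    canvas: np.ndarray,
    y: float,
    x: float,
    r_minor: float,
    r_major: float,
    rotation: float,
    value: float,
) -> None:
    """Fill a rotated ellipse on ``canvas`` in place.

    Rasterizes only the local bounding patch, which keeps per-larva cost
    small when thousands of larvae are drawn per stack.
    """
    h, w = canvas.shape
    radius = max(r_minor, r_major) + 1.0
    y0, y1 = max(int(y - radius), 0), min(int(y + radius) + 2, h)
    x0, x1 = max(int(x - radius), 0), min(int(x + radius) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None] - y
    xx = np.arange(x0, x1, dtype=float)[None, :] - x
    c, s = math.cos(rotation), math.sin(rotation)
    major = (xx * c + yy * s) / r_major
    minor = (-xx * s + yy * c) / r_minor
    canvas[y0:y1, x0:x1][major * major + minor * minor <= 1.0] = value


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] (triangle-wave reflection)."""
    span = hi - lo
    if span <= 0:
        return np.full_like(values, lo)
    v = np.mod(values - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


class _WellState:
    """Larva positions and orientations inside one well rectangle."""

    def __init__(self, rect: Rect, n: int, cfg: SimulationConfig, rng: np.random.Generator):
        margin = cfg.larva_width_px
        self.lo_y, self.hi_y = rect.top + margin, rect.bottom - 1 - margin
        self.lo_x, self.hi_x = rect.left + margin, rect.right - 1 - margin
        self.pos = np.column_stack(
            [
                rng.uniform(self.lo_y, self.hi_y, size=n),
                rng.uniform(self.lo_x, self.hi_x, size=n),
            ]
        )
        self.angle = rng.uniform(0.0, math.pi, size=n)
        self.n = n

    def advance(self, factor: float, cfg: SimulationConfig, rng: np.random.Generator) -> None:
        # dose scales drift SD and jump rate alike (paralysis hits all modes)
        step = rng.normal(0.0, cfg.motility * factor, size=self.pos.shape)
        jumping = rng.random(self.n) < cfg.jump_rate * factor
        if jumping.any():
            theta = rng.uniform(0.0, 2.0 * math.pi, size=int(jumping.sum()))
            step[jumping, 0] += cfg.jump_scale * np.sin(theta)
            step[jumping, 1] += cfg.jump_scale * np.cos(theta)
        self.pos = self.pos + step
        self.pos[:, 0] = _reflect(self.pos[:, 0], self.lo_y, self.hi_y)
        self.pos[:, 1] = _reflect(self.pos[:, 1], self.lo_x, self.hi_x)


class _PlateState:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.plate = cfg.plate_map()
        lo, hi = cfg.larvae_per_well
        self.wells: dict[str, _WellState] = {}
        for label in self.plate.wells:
            n = int(rng.integers(lo, hi + 1))
            self.wells[label] = _WellState(self.plate.rects[label], n, cfg, rng)

    def render_stack(
        self,
        factors: Mapping[str, float],
        rng: np.random.Generator,
        acquired_at_s: float,
        plate_id: str,
        timepoint_label: str,
    ) -> FrameStack:
        cfg = self.cfg
        shape = cfg.frame_shape
        frames = np.empty((cfg.frames,) + shape, dtype=np.uint8)
        for f in range(cfg.frames):
            canvas = np.full(shape, cfg.background, dtype=float)
            for label, well in self.wells.items():
                if f > 0:
                    well.advance(factors.get(label, 1.0), cfg, rng)
                for (y, x), ang in zip(well.pos, well.angle):
                    _paint_ellipse(
                        canvas,
                        y,
                        x,
                        cfg.larva_width_px / 2.0,
                        cfg.larva_length_px / 2.0,
                        ang,
                        cfg.foreground,
                    )
            if cfg.noise_sd > 0:
                canvas = canvas + rng.normal(0.0, cfg.noise_sd, size=shape)
            frames[f] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
        return FrameStack(
            frames=frames,
            frame_interval_ms=cfg.frame_interval_ms,
            acquired_at_s=acquired_at_s,
            plate_id=plate_id,
            timepoint_label=timepoint_label,
        )


def _dose_factors(
    plate: PlateMap,
    dose_map: Mapping[str, float] | None,
    true_i,
    true_h: float,
) -> dict[str, float]:
    """Per-well motility multipliers from the planted Hill curve.

    ``true_i`` may be a scalar log10 IC50 shared by every well or a per-well
    mapping (a library screen plants a different potency per compound well).
    Wells absent from ``dose_map`` (or dosed at 0) are vehicle: factor 1.
    """
    factors = {}
    for label in plate.wells:
        conc = (dose_map or {}).get(label)
        if conc is None or conc <= 0:
            factors[label] = 1.0
            continue
        i_well = true_i[label] if isinstance(true_i, Mapping) else true_i
        factors[label] = float(predict_sigmoid(math.log10(conc), i_well, true_h))
    return factors


def simulate_plate(
    config: SimulationConfig,
    dose_map: Mapping[str, float] | None = None,
    true_I: float | Mapping[str, float] = -7.0,
    true_H: float = 1.0,
    acquired_at_s: float = 0.0,
    plate_id: str = "sim-plate",
) -> tuple[FrameStack, GroundTruth]:
    """Render a single synthetic plate frame stack with known ground truth."""
    rng = np.random.default_rng(config.seed)
    state = _PlateState(config, rng)
    factors = _dose_factors(state.plate, dose_map, true_I, true_H)
    stack = state.render_stack(factors, rng, acquired_at_s, plate_id, "single")
    truth = GroundTruth(
        params={"true_I": true_I, "true_H": true_H, "seed": config.seed},
        per_well={
            label: {
                "n_larvae": state.wells[label].n,
                "motility_factor": factors[label],
                "concentration_molar": (dose_map or {}).get(label),
            }
            for label in state.plate.wells
        },
    )
    return stack, truth


def simulate_series(
    config: SimulationConfig,
    dose_map: Mapping[str, float] | None = None,
    true_I: float | Mapping[str, float] = -7.0,
    true_H: float = 1.0,
    baseline_time_s: float = -60.0,
    post_time_s: float = 14400.0,
    n_sequences: int = 5,
    plate_id: str = "sim-plate",
) -> tuple[AcquisitionSeries, GroundTruth]:
    """Baseline-plus-post acquisition of one simulated plate.

    The same larvae (counts and continuing positions) appear throughout: the
    baseline is recorded pre-compound (all wells at full motility) and the
    post acquisition at ``post_time_s`` (default 240 min) with dosed wells
    slowed by their Hill factor — exactly the structure the per-well baseline
    normalization assumes. Each timepoint is filmed as ``n_sequences``
    repeated image sequences (the standard protocol records 5-10 back to
    back), which the measurement pipeline aggregates by median; the repeats
    average out the Poisson jump events that dominate single-sequence
    variability.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = np.random.default_rng(config.seed)
    state = _PlateState(config, rng)
    vehicle = {label: 1.0 for label in state.plate.wells}
    baseline = [
        state.render_stack(vehicle, rng, baseline_time_s, plate_id, f"baseline-{i}")
        for i in range(n_sequences)
    ]
    factors = _dose_factors(state.plate, dose_map, true_I, true_H)
    post = [
        state.render_stack(factors, rng, post_time_s, plate_id, f"post-{i}")
        for i in range(n_sequences)
    ]
    series = AcquisitionSeries(baseline=baseline, post=post)
    truth = GroundTruth(
        params={"true_I": true_I, "true_H": true_H, "seed": config.seed},
        per_well={
            label: {
                "n_larvae": state.wells[label].n,
                "motility_factor": factors[label],
                "concentration_molar": (dose_map or {}).get(label),
            }
            for label in state.plate.wells
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# dose tables and decay traces

def simulate_dose_table(
    true_I: float,
    true_H: float,
    concentrations: Sequence[float],
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[list[DoseResponsePoint], GroundTruth]:
    """Noisy normalized-movement observations on a planted Hill curve."""
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for _ in range(replicates):
        for conc in concentrations:
            resp = predict_sigmoid(math.log10(conc), true_I, true_H)
            if noise_sd > 0:
                resp += rng.normal(0.0, noise_sd)
            points.append(DoseResponsePoint(conc, max(resp, 0.0)))
    truth = GroundTruth(params={"true_I": true_I, "true_H": true_H, "seed": seed})
    return points, truth


def simulate_decay_series(
    baseline_a: float,
    amplitude_b: float,
    rate_k: float,
    onset_t: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    well: str = "A1",
) -> tuple[VarianceTimeSeries, GroundTruth]:
    """Plateau-then-exponential-decay variance trace with known parameters."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly ascending")
    rng = np.random.default_rng(seed)
    values = decay_model(times, baseline_a, amplitude_b, rate_k, onset_t)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    values = np.clip(values, 0.0, None)
    series = VarianceTimeSeries(well=well, times_s=times, values=values)
    truth = GroundTruth(
        params={
            "A": baseline_a,
            "B": amplitude_b,
            "k": rate_k,
            "T": onset_t,
            "seed": seed,
        }
    )
    return series, truth
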