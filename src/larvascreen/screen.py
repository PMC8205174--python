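"""Library-screen orchestration: ranking compounds by motility reduction.

A primary screen films each plate before compound addition and again at the
assay timepoint (default 240 min), computes every well's baseline-normalized
movement index, takes the per-compound median across replicate plates, and
ranks compounds ascending — rank 1 is the strongest motility reduction. The
top-k hits are then confirmed in concentration-response plates and fitted
for pIC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dose import DoseResponsePoint, SigmoidFit, fit_sigmoid
from .imaging import AcquisitionSeries, MovementRecord
from .paragon import ParagonParams, measure_plate
from .plate import PlateMap

__all__ = [
    "CompoundAssignment",
    "CompoundWellMap",
    "ScreenRecord",
    "run_screen",
    "select_hits",
    "confirm_hits",
    "DEFAULT_ASSAY_TIME_S",
]

#: Default assay timepoint: 240 min after compound addition.
DEFAULT_ASSAY_TIME_S = 240.0 * 60.0


@dataclass(frozen=True)
class CompoundAssignment:
    compound_id: str
    concentration_molar: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.is_control and not self.concentration_molar > 0:
            raise ValueError("compound concentration must be positive")


@dataclass
class CompoundWellMap:
    """Plate layout: which compound (or vehicle control) sits in each well."""

    entries: dict[str, CompoundAssignment]

    def __post_init__(self) -> None:
        if not any(a.is_control for a in self.entries.values()):
            raise ValueError("layout must include at least one control well")

    @property
    def compounds(self) -> list[str]:
        return sorted(
            {a.compound_id for a in self.entries.values() if not a.is_control}
        )

    def wells_of(self, compound_id: str) -> list[str]:
        return [
            w
            for w, a in self.entries.items()
            if a.compound_id == compound_id and not a.is_control
        ]

    @property
    def control_wells(self) -> list[str]:
        return [w for w, a in self.entries.items() if a.is_control]


@dataclass
class ScreenRecord:
    """Per-compound screen outcome; rank 1 = strongest motility reduction."""

    compound_id: str
    median_norm_index: float
    n_replicates: int
    rank: int = 0


def _assay_records(
    series_per_replicate: Sequence[AcquisitionSeries],
    plate: PlateMap,
    params: ParagonParams | None,
    assay_time_s: float | None,
) -> list[MovementRecord]:
    """Measure every replicate and keep records at the assay timepoint."""
    if not series_per_replicate:
        raise ValueError("at least one replicate acquisition series is required")
    records: list[MovementRecord] = []
    for i, series in enumerate(series_per_replicate, start=1):
        records.extend(measure_plate(series, plate, params, replicate=i))
    if not records:
        raise ValueError("no post-compound timepoints in the acquisition series")
    times = np.array(sorted({r.timepoint_s for r in records}))
    target = DEFAULT_ASSAY_TIME_S if assay_time_s is None else assay_time_s
    chosen = float(times[np.argmin(np.abs(times - target))])
    return [r for r in records if r.timepoint_s == chosen]


def run_screen(
    series_per_replicate: Sequence[AcquisitionSeries],
    plate: PlateMap,
    layout: CompoundWellMap,
    params: ParagonParams | None = None,
    assay_time_s: float | None = None,
) -> list[ScreenRecord]:
    """Rank library compounds by median normalized movement index.

    Each compound's replicate values are the defined (non-NaN) normalized
    indices of its wells across all replicate plates; compounds with no
    defined value (e.g. empty wells throughout) are excluded with a warning.
    Ties in the median are broken lexicographically by compound id so the
    ranking is deterministic.
    """
    for well in layout.entries:
        if well not in plate.rects:
            raise ValueError(f"layout well {well} does not exist on the plate")
    records = _assay_records(series_per_replicate, plate, params, assay_time_s)
    by_well: dict[str, list[float]] = {}
    for r in records:
        if r.is_defined:
            by_well.setdefault(r.well, []).append(r.normalized_index)

    screen: list[ScreenRecord] = []
    for compound in layout.compounds:
        values = [v for w in layout.wells_of(compound) for v in by_well.get(w, [])]
        if not values:
            warnings.warn(
                f"compound {compound}: all normalized indices undefined; excluded"
            )
            continue
        screen.append(
            ScreenRecord(
                compound_id=compound,
                median_norm_index=float(np.median(values)),
                n_replicates=len(values),
            )
        )
    screen.sort(key=lambda rec: (rec.median_norm_index, rec.compound_id))
    for rank, rec in enumerate(screen, start=1):
        rec.rank = rank
    return screen


def select_hits(records: Sequence[ScreenRecord], k: int) -> list[str]:
    """The k lowest-median compounds, in rank order."""
    if not 1 <= k <= len(records):
        raise ValueError(f"k must be in [1, {len(records)}], got {k}")
    ordered = sorted(records, key=lambda rec: rec.rank)
    return [rec.compound_id for rec in ordered[:k]]


def confirm_hits(
    series_per_replicate: Sequence[AcquisitionSeries],
    plate: PlateMap,
    layout: CompoundWellMap,
    compounds: Sequence[str] | None = None,
    params: ParagonParams | None = None,
    assay_time_s: float | None = None,
) -> dict[str, SigmoidFit]:
    """Concentration-response confirmation of screen hits.

    The confirmation plate lays each compound out at multiple concentrations
    (>= 4 required). Per compound and concentration the defined normalized
    indices are medianed across wells and replicates, and the resulting
    points are fitted with the Hill curve; each compound is fitted
    independently, so results do not depend on processing order.
    """
    records = _assay_records(series_per_replicate, plate, params, assay_time_s)
    by_well: dict[str, list[float]] = {}
    for r in records:
        if r.is_defined:
            by_well.setdefault(r.well, []).append(r.normalized_index)

    fits: dict[str, SigmoidFit] = {}
    for compound in compounds if compounds is not None else layout.compounds:
        by_conc: dict[float, list[float]] = {}
        for well in layout.wells_of(compound):
            conc = layout.entries[well].concentration_molar
            by_conc.setdefault(conc, []).extend(by_well.get(well, []))
        points = [
            DoseResponsePoint(conc, float(np.median(vals)))
            for conc, vals in sorted(by_conc.items())
            if vals
        ]
        if len(points) < 4:
            raise ValueError(
                f"compound {compound}: confirmation needs >= 4 concentrations, "
                f"got {len(points)}"
            )
        fits[compound] = fit_sigmoid(points)
    return fits
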