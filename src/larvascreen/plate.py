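"""Plate geometry: mapping image pixels to wells.

Two routes are supported. The primary route is a declared rectangular grid
(rows x cols inside a bounding box, the standard 96-well layout being 8 x 12);
the fallback, mirroring the smartphone workflow, segments a pixel-variance map
into regions of interest and assigns them to wells by centroid containment.

Conventions: 0-based pixel coordinates, half-open rectangles, origin at the
image top-left; wells are labelled row-major from the top-left corner as
"A1".."H12".
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml
from skimage import measure

__all__ = [
    "Rect",
    "PlateMap",
    "Roi",
    "RoiSet",
    "build_grid",
    "auto_roi",
    "match_roi_to_wells",
    "well_label",
    "well_labels",
    "load_plate_config",
    "save_label_image",
]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [left, right) x [top, bottom)."""

    left: int
    top: int
    right: int
    bottom: int

    def __post_init__(self) -> None:
        if self.right <= self.left or self.bottom <= self.top:
            raise ValueError(f"empty rectangle: {self}")

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def height(self) -> int:
        return self.bottom - self.top

    def contains(self, y: float, x: float) -> bool:
        return self.left <= x < self.right and self.top <= y < self.bottom


def well_label(row: int, col: int) -> str:
    """Row-major well label: (0, 0) -> 'A1'. Rows beyond 'Z' use 'AA', 'AB', ..."""
    letters = string.ascii_uppercase
    if row < 26:
        prefix = letters[row]
    else:
        prefix = letters[row // 26 - 1] + letters[row % 26]
    return f"{prefix}{col + 1}"


def well_labels(rows: int, cols: int) -> list[str]:
    """All labels in row-major order (A1, A2, ..., up to the last well)."""
    return [well_label(r, c) for r in range(rows) for c in range(cols)]


@dataclass
class PlateMap:
    """Geometry mapping wells to pixel regions.

    ``rects`` gives each well's grid rectangle; ``regions`` gives the active
    pixel mask per well (boolean arrays over ``frame_shape``). For a plain
    grid the mask is the filled rectangle.
    """

    rows: int
    cols: int
    bbox: Rect
    rects: dict[str, Rect]
    frame_shape: tuple[int, int]
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = {
                label: self._rect_mask(rect) for label, rect in self.rects.items()
            }

    def _rect_mask(self, rect: Rect) -> np.ndarray:
        mask = np.zeros(self.frame_shape, dtype=bool)
        mask[rect.top : rect.bottom, rect.left : rect.right] = True
        return mask

    @property
    def wells(self) -> list[str]:
        return list(self.rects)

    def well_at(self, y: float, x: float) -> str | None:
        """Label of the well whose rectangle contains the point, if any."""
        for label, rect in self.rects.items():
            if rect.contains(y, x):
                return label
        return None


@dataclass
class Roi:
    """A connected region of interest with its centroid and pixel area."""

    mask: np.ndarray
    centroid: tuple[float, float]  # (y, x)
    area: int


@dataclass
class RoiSet:
    regions: list[Roi] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def build_grid(
    bbox: Rect | tuple[int, int, int, int],
    rows: int = 8,
    cols: int = 12,
    frame_shape: tuple[int, int] | None = None,
) -> PlateMap:
    """Partition ``bbox`` into a rows x cols grid of well rectangles.

    Integer division remainders are absorbed by the last row and column so the
    union of regions tiles the bbox exactly. Raises a geometry error when the
    grid is finer than the pixel extent.
    """
    if not isinstance(bbox, Rect):
        bbox = Rect(*bbox)
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if cols > bbox.width or rows > bbox.height:
        raise ValueError(
            f"grid {rows}x{cols} exceeds bbox pixel extent "
            f"{bbox.height}x{bbox.width}"
        )
    if frame_shape is None:
        frame_shape = (bbox.bottom, bbox.right)

    cell_w = bbox.width // cols
    cell_h = bbox.height // rows
    rects: dict[str, Rect] = {}
    for r in range(rows):
        top = bbox.top + r * cell_h
        bottom = bbox.bottom if r == rows - 1 else top + cell_h
        for c in range(cols):
            left = bbox.left + c * cell_w
            right = bbox.right if c == cols - 1 else left + cell_w
            rects[well_label(r, c)] = Rect(left, top, right, bottom)
    return PlateMap(
        rows=rows, cols=cols, bbox=bbox, rects=rects, frame_shape=frame_shape
    )


def auto_roi(
    vmap: np.ndarray,
    threshold_quantile: float = 0.95,
    min_area: int = 20,
) -> RoiSet:
    """Segment a variance map into regions of interest.

    Pixels strictly above the given quantile of the variance distribution are
    foreground; 8-connected components with area >= ``min_area`` are returned
    sorted row-major by centroid. Quantile thresholding makes the result
    invariant to positive rescaling of the map. An all-zero map yields an
    empty set.
    """
    values = np.asarray(getattr(vmap, "values", vmap), dtype=float)
    if values.min() < 0:
        raise ValueError("variance map must be non-negative")
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    cutoff = np.quantile(values, threshold_quantile)
    foreground = values > cutoff
    labels = measure.label(foreground, connectivity=2)
    rois = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        rois.append(
            Roi(
                mask=labels == prop.label,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
            )
        )
    rois.sort(key=lambda roi: (roi.centroid[0], roi.centroid[1]))
    return RoiSet(rois)


def match_roi_to_wells(rois: RoiSet, plate: PlateMap) -> dict[str, np.ndarray]:
    """Assign each ROI to the well whose rectangle contains its centroid.

    ROIs falling outside every well are dropped; two ROIs in one well are
    unioned; wells with no ROI fall back to their full grid rectangle, so the
    mapping always covers all wells.
    """
    masks = {label: plate.regions[label].copy() for label in plate.wells}
    claimed: set[str] = set()
    for roi in rois:
        label = plate.well_at(*roi.centroid)
        if label is None:
            continue
        mask = np.zeros(plate.frame_shape, dtype=bool)
        h = min(roi.mask.shape[0], plate.frame_shape[0])
        w = min(roi.mask.shape[1], plate.frame_shape[1])
        mask[:h, :w] = roi.mask[:h, :w]
        if label in claimed:
            masks[label] |= mask
        else:
            masks[label] = mask
            claimed.add(label)
    return masks


def load_plate_config(path: str | Path) -> tuple[PlateMap, dict]:
    """Read a YAML or JSON plate config.

    Expected keys: ``rows``, ``cols``, ``bbox`` (left, top, right, bottom) and
    optionally ``frame_shape`` (H, W) and a per-well ``layout`` table, which is
    returned verbatim as the second element.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    bbox = Rect(*cfg["bbox"])
    frame_shape = tuple(cfg["frame_shape"]) if "frame_shape" in cfg else None
    plate = build_grid(
        bbox,
        rows=int(cfg.get("rows", 8)),
        cols=int(cfg.get("cols", 12)),
        frame_shape=frame_shape,
    )
    return plate, cfg.get("layout", {})


def save_label_image(
    plate_or_masks: PlateMap | Mapping[str, np.ndarray], path: str | Path
) -> Path:
    """Export well masks as a label-image TIFF (0 = background, wells 1..N)."""
    masks = (
        plate_or_masks.regions
        if isinstance(plate_or_masks, PlateMap)
        else plate_or_masks
    )
    first = next(iter(masks.values()))
    label_img = np.zeros(first.shape, dtype=np.uint16)
    for i, (_, mask) in enumerate(masks.items(), start=1):
        label_img[mask] = i
    path = Path(path)
    tifffile.imwrite(path, label_img)
    return path
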