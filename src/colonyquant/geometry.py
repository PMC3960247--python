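"""Well grid construction, inter-well masking and concentric cropping.

Wells are located purely from arithmetic: the user supplies a rectangular
selection that encloses the wells to analyse plus the plate type, and the
well centres are placed on a uniform lattice filling that rectangle.  No
image-based circle detection is attempted — scanned plates are assumed
axis-aligned with evenly spaced circular wells.

Each well is then *concentrically cropped*: its analysis disc is shrunk to
95% of the nominal well diameter by default, excluding the well rim where
cells grow abnormally (edge effects, meniscus shading).
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .plate_io import PlateImage

__all__ = [
    "PlateLayout",
    "WellROI",
    "WellImage",
    "BUILTIN_LAYOUTS",
    "get_layout",
    "well_id",
    "parse_well_range",
    "grid_from_selection",
    "mask_interwell",
    "crop_well_stack",
]

#: Default fraction by which each well diameter is reduced before analysis.
DEFAULT_CROP_FRACTION = 0.05


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well plate.

    ``well_diameter`` and ``well_pitch`` (centre-to-centre spacing) are in
    millimetres; only their ratio matters for grid construction, the
    absolute values matter when sizing synthetic plates from a dpi.
    """

    name: str
    rows: int
    cols: int
    well_diameter: float
    well_pitch: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("plate layout needs at least one row and column")
        if not 0 < self.well_diameter < self.well_pitch:
            raise ValidationError(
                "well diameter must be positive and smaller than the pitch"
            )

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols


# Nominal CELLSTAR-style dimensions (mm); overridable with a custom layout.
BUILTIN_LAYOUTS: dict[str, PlateLayout] = {
    "6-well": PlateLayout("6-well", 2, 3, 34.8, 39.12),
    "12-well": PlateLayout("12-well", 3, 4, 22.1, 26.01),
    "24-well": PlateLayout("24-well", 4, 6, 15.6, 19.3),
}


def get_layout(spec: str | int | PlateLayout) -> PlateLayout:
    """Resolve ``6 | 12 | 24 | "12-well" | PlateLayout`` to a layout."""
    if isinstance(spec, PlateLayout):
        return spec
    key = f"{spec}-well" if isinstance(spec, int) else str(spec)
    if key not in BUILTIN_LAYOUTS:
        raise ValidationError(
            f"unknown plate layout {spec!r}; built-ins: {sorted(BUILTIN_LAYOUTS)}"
        )
    return BUILTIN_LAYOUTS[key]


def well_id(row: int, col: int) -> str:
    """Row-letter + column-number label, 0-based indices → 'A1' style."""
    return f"{string.ascii_uppercase[row]}{col + 1}"


_WELL_RE = re.compile(r"^([A-Z])(\d+)$")


def _parse_well(wid: str) -> tuple[int, int]:
    m = _WELL_RE.match(wid.strip().upper())
    if not m:
        raise ValidationError(f"malformed well id {wid!r} (expected e.g. 'A1')")
    return string.ascii_uppercase.index(m.group(1)), int(m.group(2)) - 1


def parse_well_range(spec: str) -> list[str]:
    """Expand ``"A1:C4"`` to the row-major list of well ids in that block.

    A comma-separated list of ids (``"A1,B2"``) is also accepted.
    """
    spec = spec.strip()
    if ":" in spec:
        lo, hi = spec.split(":", 1)
        (r0, c0), (r1, c1) = _parse_well(lo), _parse_well(hi)
        r0, r1 = sorted((r0, r1))
        c0, c1 = sorted((c0, c1))
        return [well_id(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]
    return [w.strip().upper() for w in spec.split(",") if w.strip()]


@dataclass(frozen=True)
class WellROI:
    """One well's circular region of interest in plate-image coordinates."""

    well_id: str
    centre: tuple[float, float]  # (x, y), pixels
    radius: float  # nominal well radius, pixels

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"well {self.well_id}: radius must be positive")


@dataclass
class WellImage:
    """A square crop of one well with its circular analysis mask.

    ``origin`` is the (x, y) plate-image coordinate of the crop's top-left
    pixel, kept so sub-regions and ground-truth grids can be mapped back.
    Pixels outside ``mask`` are carried for display but ignored by every
    downstream statistic.
    """

    well_id: str
    pixels: np.ndarray  # uint8, square
    mask: np.ndarray  # bool, same shape
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValidationError(
                f"well {self.well_id}: pixels and mask shapes differ"
            )

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


def _sub_grid_shape(selected: list[str]) -> tuple[list[str], int, int]:
    """Validate that the ids form a contiguous r x c block, row-major order."""
    coords = {wid.upper(): _parse_well(wid) for wid in selected}
    if len(coords) != len(selected):
        raise ValidationError("duplicate well ids in selection")
    rows = sorted({r for r, _ in coords.values()})
    cols = sorted({c for _, c in coords.values()})
    if rows != list(range(rows[0], rows[-1] + 1)) or cols != list(
        range(cols[0], cols[-1] + 1)
    ):
        raise ValidationError("selected wells must form a contiguous rectangular block")
    if len(coords) != len(rows) * len(cols):
        raise ValidationError("selected wells must fill the rectangular block")
    ordered = [
        well_id(r, c) for r in range(rows[0], rows[-1] + 1)
        for c in range(cols[0], cols[-1] + 1)
    ]
    return ordered, len(rows), len(cols)


def grid_from_selection(
    selection: tuple[float, float, float, float],
    layout: PlateLayout,
    selected_wells: list[str] | None = None,
) -> list[WellROI]:
    """Place well centres on a uniform lattice filling a rectangular selection.

    ``selection`` is ``(x0, y0, x1, y1)`` in pixel coordinates.  With no
    ``selected_wells`` the full ``layout.rows x layout.cols`` grid is
    assumed; otherwise the ids must form a contiguous sub-grid, and the
    lattice has that sub-grid's shape.  The nominal well radius is
    ``(well_diameter / well_pitch) x (lattice cell span / 2)`` using the
    smaller of the x/y spans, so the pixel scale is inferred from the
    selection itself rather than from the dpi.

    Returns ROIs in row-major order (A1, A2, ...).
    """
    x0, y0, x1, y1 = map(float, selection)
    if not (x1 > x0 and y1 > y0):
        raise ValidationError("selection rectangle must have positive width and height")
    if selected_wells is None:
        ids = [well_id(r, c) for r in range(layout.rows) for c in range(layout.cols)]
        nrows, ncols = layout.rows, layout.cols
    else:
        ids, nrows, ncols = _sub_grid_shape(list(selected_wells))
        if nrows > layout.rows or ncols > layout.cols:
            raise ValidationError("selected block exceeds the plate layout")
    span_x = (x1 - x0) / ncols
    span_y = (y1 - y0) / nrows
    radius = (layout.well_diameter / layout.well_pitch) * min(span_x, span_y) / 2.0
    if radius < 1:
        raise ValidationError("selection is too small for the implied well grid")
    rois = []
    for i in range(nrows):
        for j in range(ncols):
            cx = x0 + (j + 0.5) * span_x
            cy = y0 + (i + 0.5) * span_y
            rois.append(WellROI(ids[i * ncols + j], (cx, cy), radius))
    return rois


def _disc_mask(shape, centre, radius, origin=(0, 0)):
    """Boolean membership grid: (x-cx)^2 + (y-cy)^2 < r^2 at pixel centres."""
    h, w = shape
    ox, oy = origin
    ys = np.arange(oy, oy + h, dtype=float)[:, None]
    xs = np.arange(ox, ox + w, dtype=float)[None, :]
    cx, cy = centre
    return (xs - cx) ** 2 + (ys - cy) ** 2 < radius**2


def mask_interwell(image: PlateImage, grid: list[WellROI]) -> PlateImage:
    """Zero every pixel outside all nominal well discs.

    Purely cosmetic/QC for the pipeline proper: downstream statistics only
    ever look inside the cropped analysis discs, which are strict subsets
    of the nominal discs.
    """
    if not grid:
        raise ValidationError("well grid is empty")
    keep = np.zeros(image.shape, dtype=bool)
    for roi in grid:
        keep |= _disc_mask(image.shape, roi.centre, roi.radius)
    pixels = np.where(keep, image.pixels, 0).astype(np.uint8)
    return PlateImage(pixels, dpi=image.dpi, source=image.source)


def crop_well_stack(
    image: PlateImage,
    grid: list[WellROI],
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> list[WellImage]:
    """Cut each well into a square :class:`WellImage` with a reduced disc mask.

    The analysis radius is ``nominal radius x (1 - crop_fraction)``; the
    default 0.05 shrinks each well diameter by 5%, trimming the rim.  Wells
    are returned in grid order.
    """
    if not 0 <= crop_fraction < 1:
        raise ValidationError("crop_fraction must lie in [0, 1)")
    h, w = image.shape
    out = []
    for roi in grid:
        cx, cy = roi.centre
        r = roi.radius * (1.0 - crop_fraction)
        x_lo = int(math.floor(cx - r)) + 1
        x_hi = int(math.ceil(cx + r)) - 1
        y_lo = int(math.floor(cy - r)) + 1
        y_hi = int(math.ceil(cy + r)) - 1
        # square up: pad the shorter axis, preferring the high side
        wx, wy = x_hi - x_lo + 1, y_hi - y_lo + 1
        side = max(wx, wy)
        x_lo -= (side - wx) // 2
        x_hi = x_lo + side - 1
        y_lo -= (side - wy) // 2
        y_hi = y_lo + side - 1
        if x_lo < 0 or y_lo < 0 or x_hi >= w or y_hi >= h:
            raise ValidationError(
                f"well {roi.well_id}: analysis disc extends beyond the image"
            )
        mask = _disc_mask((side, side), (cx, cy), r, origin=(x_lo, y_lo))
        pixels = image.pixels[y_lo : y_hi + 1, x_lo : x_hi + 1].copy()
        out.append(WellImage(roi.well_id, pixels, mask, origin=(x_lo, y_lo)))
    return out
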