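"""Colony area and colony intensity percentages.

Two statistics summarise each thresholded well (or a rectangular
sub-region of it):

* **colony area percentage** — the fraction of analysed pixels classified
  as cells::

      area% = 100 * #{pixels with density > 0} / #{analysed pixels}

* **colony intensity percentage** — the same coverage weighted by the
  inverted staining intensity, normalised to full saturation::

      intensity% = 100 * sum(density) / (255 * #{analysed pixels})

  Since every cell pixel contributes at most 255 to the numerator,
  ``intensity% <= area%`` always; the gap between the two reflects how
  densely stained (how cell-dense) the covered area is.

The analysed pixel set is the circular analysis mask, optionally
intersected with a user rectangle — the sub-region escape hatch for scans
with shading, where only part of a well was thresholded correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_io import MEASUREMENT_COLUMNS
from .thresholding import ThresholdedWell, ThresholdResult

__all__ = [
    "Region",
    "FULL_WELL",
    "colony_area_pct",
    "colony_intensity_pct",
    "measure_stack",
]


@dataclass(frozen=True)
class Region:
    """Analysis region: the full circular mask, or its intersection with a
    rectangle ``(x0, y0, x1, y1)`` in well-local pixel coordinates
    (half-open, ``x0 <= x < x1``)."""

    rect: tuple[int, int, int, int] | None = None

    def describe(self) -> str:
        if self.rect is None:
            return "full"
        return "rect:{},{},{},{}".format(*self.rect)

    def resolve(self, tw: ThresholdedWell) -> np.ndarray:
        region = tw.mask.copy()
        if self.rect is not None:
            x0, y0, x1, y1 = self.rect
            if not (x1 > x0 and y1 > y0):
                raise ValidationError("sub-region rectangle must be non-degenerate")
            box = np.zeros_like(region)
            box[max(y0, 0) : y1, max(x0, 0) : x1] = True
            region &= box
        if not region.any():
            raise ValidationError(
                f"well {tw.well_id}: region {self.describe()} contains no pixels"
            )
        return region


FULL_WELL = Region()


def colony_area_pct(tw: ThresholdedWell, region: Region = FULL_WELL) -> float:
    """Percentage of region pixels classified as cells (density > 0)."""
    m = region.resolve(tw)
    return 100.0 * np.count_nonzero(tw.density[m]) / np.count_nonzero(m)


def colony_intensity_pct(tw: ThresholdedWell, region: Region = FULL_WELL) -> float:
    """Density-weighted coverage, normalised to fully saturated staining."""
    m = region.resolve(tw)
    n = np.count_nonzero(m)
    return 100.0 * float(tw.density[m].astype(np.int64).sum()) / (255.0 * n)


def measure_stack(
    tws: list[ThresholdedWell],
    results: list[ThresholdResult] | None = None,
    region: Region = FULL_WELL,
    subset: set[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-well measurement table.

    One row per (selected) well with both statistics; thresholds, methods
    and consistency-check flags are carried through from ``results``.
    ``subset`` restricts the rows, e.g. for sub-region reanalysis of a few
    wells only.
    """
    if results is not None and len(results) != len(tws):
        raise ValidationError("thresholded wells and results are not aligned")
    known = {tw.well_id for tw in tws}
    if subset is not None:
        unknown = sorted(set(subset) - known)
        if unknown:
            raise ValidationError(f"unknown well ids in subset: {unknown}")
    rows = []
    for i, tw in enumerate(tws):
        if subset is not None and tw.well_id not in subset:
            continue
        res = results[i] if results is not None else None
        m = region.resolve(tw)
        rows.append(
            {
                "well_id": tw.well_id,
                "area_pct": colony_area_pct(tw, region),
                "intensity_pct": colony_intensity_pct(tw, region),
                "threshold": res.threshold if res else -1,
                "threshold_method": res.method if res else "unknown",
                "flags": "consistency" if (res and res.flagged) else "",
                "region": region.describe(),
                "n_pixels": int(np.count_nonzero(m)),
            }
        )
    if not rows:
        raise ValidationError("no wells selected for measurement")
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS + ["region", "n_pixels"])
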