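"""Reading scanner images and writing tabular / QC outputs.

A plate scan enters the pipeline as a :class:`PlateImage`: an 8-bit greyscale
raster plus the scan resolution (dpi), which links the plate's millimetre
geometry to pixel coordinates.  Colour scans are converted to grey on read;
16-bit scans are linearly rescaled to the 8-bit range.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "PlateImage",
    "MEASUREMENT_COLUMNS",
    "read_scan",
    "to_grayscale_8bit",
    "write_measurements",
    "read_measurements",
    "write_well_montage",
]

#: Fixed column order of the measurement CSV.
MEASUREMENT_COLUMNS = [
    "well_id",
    "area_pct",
    "intensity_pct",
    "threshold",
    "threshold_method",
    "flags",
]


def _round_half_up(x):
    """Round to nearest integer, halves away from zero-wards (half-up)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class PlateImage:
    """One scanned multi-well plate as an 8-bit greyscale raster.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Grey intensities, 0 (black) to 255 (white).  Stained colonies are
        dark on a light background.
    dpi : float
        Scan resolution in dots per inch; must be positive.
    source : str
        Provenance label (file path or generator description).
    """

    pixels: np.ndarray
    dpi: float
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("plate image must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("plate image intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.dpi > 0:
            raise ValidationError(f"dpi must be positive, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale_8bit(rgb: np.ndarray, method: str = "mean") -> np.ndarray:
    """Convert an RGB raster to 8-bit grey.

    The default is the unweighted channel mean ``(r + g + b) / 3`` with
    half-up rounding, matching the plain 8-bit conversion of common image
    software; ``method="rec601"`` selects the luma weighting
    ``0.299 r + 0.587 g + 0.114 b`` instead.

    Already-grey triples ``(v, v, v)`` map to ``v`` under either method.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] not in (3, 4):
        raise ValidationError("expected an (H, W, 3) or (H, W, 4) RGB(A) array")
    rgb = rgb[..., :3]
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValidationError("channel values must lie in [0, 255]")
    if method == "mean":
        grey = rgb.mean(axis=-1)
    elif method == "rec601":
        grey = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise ConfigurationError(f"unknown grey conversion method {method!r}")
    return np.clip(_round_half_up(grey), 0, 255).astype(np.uint8)


def _rescale_16bit(pixels: np.ndarray) -> np.ndarray:
    """Min-max rescale a >8-bit raster linearly onto [0, 255] (half-up)."""
    pixels = pixels.astype(float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    return _round_half_up((pixels - lo) * 255.0 / (hi - lo)).astype(np.uint8)


def _tiff_dpi(path: str) -> float | None:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value if isinstance(xres.value, tuple) else (xres.value, 1)
        if den == 0 or num == 0:
            return None
        res = num / den
        unit_val = getattr(unit.value, "value", unit.value) if unit is not None else 2
        if unit_val == 3:  # centimetre
            res *= 2.54
        elif unit_val not in (2,):  # 2 = inch; 1/None = unitless
            return None
        return float(res)


def read_scan(path: str | os.PathLike, dpi_override: float | None = None) -> PlateImage:
    """Read a TIFF or PNG plate scan as an 8-bit greyscale :class:`PlateImage`.

    Colour images are converted with :func:`to_grayscale_8bit`; 16-bit
    greyscale images are min-max rescaled onto [0, 255].  The dpi is taken
    from the file's resolution metadata unless ``dpi_override`` is given;
    if the file carries none and no override is supplied a
    :class:`~colonyquant.errors.ConfigurationError` is raised.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    dpi: float | None = None
    if ext in (".tif", ".tiff"):
        import tifffile

        try:
            pixels = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - normalise decoder errors
            raise FormatError(f"could not decode TIFF {path!r}: {exc}") from exc
        dpi = _tiff_dpi(path)
    elif ext == ".png":
        from PIL import Image

        try:
            with Image.open(path) as im:
                im.load()
                info_dpi = im.info.get("dpi")
                pixels = np.asarray(im)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not decode PNG {path!r}: {exc}") from exc
        if info_dpi and info_dpi[0]:
            dpi = float(info_dpi[0])
    else:
        raise FormatError(f"unsupported image format {ext!r} (expected TIFF or PNG)")

    if dpi_override is not None:
        if not dpi_override > 0:
            raise ConfigurationError("dpi_override must be positive")
        dpi = float(dpi_override)
    if dpi is None:
        raise ConfigurationError(
            f"{path!r} carries no resolution metadata; pass dpi_override"
        )

    if pixels.ndim == 3:
        grey = to_grayscale_8bit(
            pixels if pixels.dtype == np.uint8 else _rescale_16bit_rgb(pixels)
        )
    elif pixels.dtype == np.uint8:
        grey = pixels
    else:
        grey = _rescale_16bit(pixels)
    return PlateImage(grey, dpi=dpi, source=path)


def _rescale_16bit_rgb(pixels: np.ndarray) -> np.ndarray:
    flat = _rescale_16bit(pixels.reshape(-1))
    return flat.reshape(pixels.shape)


def write_measurements(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a measurement table to CSV in the fixed column order.

    Percentages are written at full floating-point precision so that
    ``read_measurements(write_measurements(T)) == T`` bit-exactly.
    """
    if table is None or len(table) == 0:
        raise ValidationError("measurement table is empty")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measurement table lacks columns {missing}")
    if table["well_id"].duplicated().any():
        raise ValidationError("well ids must be unique")
    extras = [c for c in table.columns if c not in MEASUREMENT_COLUMNS]
    ordered = table[MEASUREMENT_COLUMNS + extras]
    try:
        ordered.to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise FormatError(f"could not write {os.fspath(path)!r}: {exc}") from exc


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{os.fspath(path)!r} lacks measurement columns {missing}")
    return df


def write_well_montage(before, after, path: str | os.PathLike) -> None:
    """Write a before/after QC montage of the well stack.

    One row per well: left panel the cropped 8-bit well image, right panel
    the thresholded, intensity-inverted density image.  This is the visual
    check that background identification succeeded in every well.
    """
    before = list(before)
    after = list(after)
    if len(before) == 0:
        raise ValidationError("montage requires at least one well")
    if len(before) != len(after):
        raise ValidationError(
            f"before/after stacks differ in length ({len(before)} vs {len(after)})"
        )
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(before)
    fig, axes = plt.subplots(n, 2, figsize=(4.2, 2.1 * n), squeeze=False)
    for i, (w, tw) in enumerate(zip(before, after)):
        ax_b, ax_a = axes[i]
        ax_b.imshow(np.where(w.mask, w.pixels, 255), cmap="gray", vmin=0, vmax=255)
        ax_b.set_ylabel(w.well_id, rotation=0, labelpad=16, va="center")
        ax_a.imshow(tw.density, cmap="inferno", vmin=0, vmax=255)
        for ax in (ax_b, ax_a):
            ax.set_xticks([])
            ax.set_yticks([])
    axes[0][0].set_title("scan")
    axes[0][1].set_title("thresholded")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
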