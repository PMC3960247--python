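"""Per-well background thresholding from the area-vs-threshold curve.

Crystal-violet stained colonies are dark on a light background, so the
cumulative histogram of a well — the *colony area percentage* ``A(t)`` of
masked pixels with intensity ``<= t`` — rises slowly through the colony
intensities, stays flat across the empty gap, and jumps towards 100% once
``t`` reaches the background mode.  The background threshold is the valley
of the intensity histogram just below that jump: the first discrete
derivative ``dA`` is the (percentage) histogram itself, its global maximum
marks the background mode, and the minimum of ``dA`` below that peak marks
the valley.  Pixels at or below the valley are called cells.

Because noisy histograms can show several local minima, per-plate
thresholds undergo a consistency check: each well's threshold is rescaled
as if the well's maximum intensity were 200, thresholds deviating more
than a tolerance (default 50 intensity units) from the plate mean are
flagged, and flagged wells are re-thresholded with the search restricted
to the plate mean ± tolerance window mapped back to native intensities.

Thresholded wells are finally inverted into *density images*: background
pixels become 0 and cell pixels ``255 - intensity`` (1–255), so higher
values mean denser staining.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .geometry import WellImage

__all__ = [
    "ThresholdCurve",
    "ThresholdResult",
    "ThresholdedWell",
    "area_threshold_curve",
    "detect_threshold",
    "harmonize_thresholds",
    "apply_threshold_invert",
    "manual_threshold",
]

#: Target maximum intensity for the cross-well comparison of thresholds.
SCALE_TARGET = 200
#: Default flagging tolerance of the consistency check, intensity units.
DEFAULT_TOLERANCE = 50


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ThresholdCurve:
    """Colony-area-percentage-vs-threshold function of one well.

    ``A[t]`` is the percentage of masked pixels with intensity ``<= t``
    (so ``A`` is non-decreasing with ``A[255] == 100``); ``dA`` and
    ``d2A`` are backward first and second differences with
    ``dA[0] = A[0]``, making ``dA`` the percentage histogram
    (``sum(dA) == 100``).
    """

    A: np.ndarray
    dA: np.ndarray
    d2A: np.ndarray

    @property
    def max_intensity(self) -> int:
        """Largest intensity actually present among the masked pixels."""
        nz = np.nonzero(self.dA > 0)[0]
        return int(nz[-1]) if nz.size else 0


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of background detection for one well.

    ``method`` is ``auto`` (derivative analysis on the full range),
    ``restricted`` (re-evaluated inside the consistency-check window),
    ``manual`` (user supplied) or ``no_colonies`` (no cell mass below the
    background mode; downstream statistics are 0).
    """

    threshold: int
    scaled_threshold: float
    max_intensity: int
    method: str = "auto"
    flagged: bool = False


@dataclass
class ThresholdedWell:
    """Background-zeroed, intensity-inverted density image of one well.

    ``density`` is 0 exactly where the original intensity exceeded the
    threshold (background) and ``255 - intensity`` (>= 1) on cell pixels.
    """

    well_id: str
    density: np.ndarray  # uint8
    mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.density.shape != self.mask.shape:
            raise ValidationError(f"well {self.well_id}: density/mask shape mismatch")


def _backward_diff(v: np.ndarray) -> np.ndarray:
    d = np.empty_like(v)
    d[0] = v[0]
    d[1:] = np.diff(v)
    return d


def area_threshold_curve(well: WellImage) -> ThresholdCurve:
    """Compute ``A(t)`` over the well's masked pixels, plus its derivatives."""
    vals = well.masked_values
    if vals.size == 0:
        raise ValidationError(f"well {well.well_id}: analysis mask is empty")
    hist = np.bincount(vals.astype(np.int64), minlength=256)
    A = 100.0 * np.cumsum(hist) / vals.size
    dA = _backward_diff(A)
    return ThresholdCurve(A=A, dA=dA, d2A=_backward_diff(dA))


def _smooth(dA: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return dA.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(dA, kernel, mode="same")


def _argmax_high(v: np.ndarray) -> int:
    """Index of the maximum; ties resolved towards the highest index."""
    return len(v) - 1 - int(np.argmax(v[::-1]))


def detect_threshold(
    curve: ThresholdCurve,
    search_range: tuple[int, int] = (0, 255),
    min_cell_area: float = 0.0,
    smooth_window: int = 3,
    rel_depth: float = 0.1,
    peak_frac: float = 0.05,
) -> ThresholdResult:
    """Locate the background threshold at the histogram valley.

    The percentage histogram ``dA`` is smoothed with a centred moving
    average (window 3 by default).  The background mode is the mode at
    *high* intensity: its peak is taken as the highest intensity inside
    ``search_range`` whose smoothed density reaches at least
    ``peak_frac`` of the global maximum (densely stained colonies can
    out-peak the background per bin, but they sit at low intensity).
    The threshold is then the transition point at the foot of the
    background surge: the highest intensity strictly below the peak
    that is a (weak) local minimum of the smoothed histogram and whose
    depth is at most ``rel_depth`` of the peak height.  The depth
    condition skips the shallow wiggles a noisy histogram shows inside
    the background mode itself; if no minimum is deep enough (heavily
    overlapping modes) the global minimum below the peak is used, ties
    resolved towards the peak.  If the curve carries no cell mass below
    the valley (``A[valley] <= min_cell_area``, in area-percent) the
    well is reported as ``no_colonies`` with the threshold at the
    largest intensity whose cumulative area is zero.
    """
    lo, hi = int(search_range[0]), int(search_range[1])
    if not (0 <= lo <= hi <= 255):
        raise ValidationError(f"invalid search range ({lo}, {hi})")
    dAs = _smooth(curve.dA, smooth_window)
    seg = dAs[lo : hi + 1]
    qualifying = np.nonzero(seg >= peak_frac * seg.max())[0]
    peak = lo + int(qualifying[-1])
    max_int = curve.max_intensity

    def _result(threshold: int, method: str) -> ThresholdResult:
        scaled = (
            threshold * SCALE_TARGET / max_int if max_int > 0 else float(threshold)
        )
        return ThresholdResult(
            threshold=threshold,
            scaled_threshold=scaled,
            max_intensity=max_int,
            method=method,
        )

    def _no_colonies() -> ThresholdResult:
        zeros = np.nonzero(curve.A[lo : hi + 1] <= 0)[0]
        t = lo + int(zeros[-1]) if zeros.size else lo
        return _result(t, "no_colonies")

    if peak == lo:  # nothing below the background mode to separate
        return _no_colonies()
    valley = None
    depth_cap = rel_depth * dAs[peak]
    for m in range(peak - 1, lo - 1, -1):
        if dAs[m] > depth_cap or dAs[m] > dAs[m + 1]:
            continue
        if m > lo and dAs[m] > dAs[m - 1]:
            continue
        valley = m
        break
    if valley is None:  # no deep valley: fall back to the global minimum
        valley = lo + _argmax_high(-dAs[lo:peak])
    if curve.A[valley] <= min_cell_area:
        return _no_colonies()
    return _result(valley, "auto")


def harmonize_thresholds(
    wells: list[WellImage],
    initial: list[ThresholdResult],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[ThresholdResult]:
    """Cross-well consistency check of the detected thresholds.

    Each threshold is linearly rescaled as if its well's maximum masked
    intensity were 200 (countering non-uniform illumination between
    wells), the plate mean of the scaled thresholds is taken, and wells
    deviating from it by more than ``tolerance`` units are flagged and
    re-thresholded with the derivative analysis restricted to the window
    ``mean ± tolerance`` mapped back to the well's native intensities.
    Wells without colonies keep their result and do not enter the mean.
    Scaled thresholds stay real-valued during the comparison; rounding
    happens only when the window is mapped back (half-up).
    """
    if len(wells) != len(initial):
        raise ValidationError("wells and initial thresholds are not aligned")
    if len(wells) < 2:
        return list(initial)
    eligible = [r.method != "no_colonies" for r in initial]
    scaled = np.array([r.scaled_threshold for r in initial], dtype=float)
    if not any(eligible):
        return list(initial)
    mean = scaled[np.array(eligible)].mean()
    out: list[ThresholdResult] = []
    for well, res, ok in zip(wells, initial, eligible):
        if not ok or abs(res.scaled_threshold - mean) <= tolerance:
            out.append(res)
            continue
        factor = res.max_intensity / SCALE_TARGET if res.max_intensity > 0 else 1.0
        lo = max(0, _round_half_up((mean - tolerance) * factor))
        hi = min(255, _round_half_up((mean + tolerance) * factor))
        redo = detect_threshold(area_threshold_curve(well), search_range=(lo, hi))
        method = "restricted" if redo.method != "no_colonies" else "no_colonies"
        out.append(replace(redo, method=method, flagged=True))
    return out


def apply_threshold_invert(well: WellImage, threshold: int) -> ThresholdedWell:
    """Zero the background and invert cell intensities into densities.

    Masked pixels with intensity ``<= threshold`` (inclusive) become
    ``255 - intensity`` (at least 1, since ``threshold <= 254``); all
    other pixels become 0.
    """
    if not 0 <= threshold <= 254:
        raise ValidationError(
            f"threshold must lie in [0, 254], got {threshold} "
            "(255 would classify pure white as cells)"
        )
    density = np.zeros(well.pixels.shape, dtype=np.uint8)
    cells = well.mask & (well.pixels <= threshold)
    density[cells] = 255 - well.pixels[cells]
    return ThresholdedWell(well.well_id, density, well.mask.copy())


def manual_threshold(
    wells: list[WellImage],
    threshold: int | dict[str, int],
) -> tuple[list[ThresholdedWell], list[ThresholdResult]]:
    """Apply a user-chosen threshold (global or per-well map) to a stack.

    Returns the thresholded wells together with ``ThresholdResult`` records
    whose method is ``manual``.
    """
    if isinstance(threshold, dict):
        missing = [w.well_id for w in wells if w.well_id not in threshold]
        if missing:
            raise ValidationError(f"manual threshold map lacks wells {missing}")
        per_well = [int(threshold[w.well_id]) for w in wells]
    else:
        per_well = [int(threshold)] * len(wells)
    tws, results = [], []
    for well, t in zip(wells, per_well):
        tws.append(apply_threshold_invert(well, t))
        max_int = int(well.masked_values.max()) if well.masked_values.size else 0
        scaled = t * SCALE_TARGET / max_int if max_int > 0 else float(t)
        results.append(
            ThresholdResult(
                threshold=t,
                scaled_threshold=scaled,
                max_intensity=max_int,
                method="manual",
            )
        )
    return tws, results
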