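"""Synthetic plate scans and dose-response data with known ground truth.

The generator emulates what a flatbed scan of a crystal-violet stained
multi-well plate looks like to the pipeline: a light intra-well
background, darker inter-well plastic, colonies as dark circular blobs
whose darkness scales with cell density, an optional linear shading
gradient (non-uniform illumination) and additive Gaussian noise.  Truth
is computed from the rendered raster — the per-pixel colony label grid —
not from the requested coverage, so pipeline-exactness tests can compare
measured statistics against exact pixel counts.

Colonies are placed as non-overlapping hard discs by random sequential
placement, which caps the attainable coverage well below 1 (the random
disc packing limit is ~0.55); image-level simulations therefore keep
target coverages at or below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .dose_response import DoseResponseModel, ll4
from .geometry import (
    DEFAULT_CROP_FRACTION,
    PlateLayout,
    WellROI,
    _disc_mask,
    get_layout,
    grid_from_selection,
)
from .plate_io import PlateImage

__all__ = [
    "SyntheticWellSpec",
    "SyntheticTruth",
    "render_plate",
    "simulate_dose_response",
    "render_dose_response_plates",
]

#: Intensity of the inter-well plastic: mid-grey, distinct from both the
#: light background and the dark colonies so masking errors are visible.
INTERWELL_INTENSITY = 140

#: Coverage beyond this is refused: hard-disc sequential placement jams.
MAX_COVERAGE = 0.5


@dataclass(frozen=True)
class SyntheticWellSpec:
    """Request for one synthetic well.

    ``target_coverage`` is the fraction of the analysis disc to cover with
    colonies; placement stops once it is reached, so the rendered coverage
    overshoots by at most one colony.  Colony intensities (uniform per
    colony) are drawn from ``colony_intensity_range`` and must stay darker
    than ``background_intensity``.
    """

    target_coverage: float
    colony_radius_range: tuple[float, float] = (2.0, 6.0)
    colony_intensity_range: tuple[int, int] = (60, 100)
    background_intensity: int = 220
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.target_coverage <= 1:
            raise ValidationError("target_coverage must lie in [0, 1]")
        if self.colony_intensity_range[1] >= self.background_intensity:
            raise ValidationError("colonies must be darker than the background")


@dataclass
class SyntheticTruth:
    """Ground truth of a rendered plate.

    ``area_fraction`` / ``intensity_fraction`` are computed inside each
    well's analysis mask on the noiseless, unshaded raster;
    ``labels`` marks colony pixels in plate coordinates.
    """

    area_fraction: dict[str, float]
    intensity_fraction: dict[str, float]
    n_colonies: dict[str, int]
    labels: np.ndarray  # bool, plate shape
    grid: list[WellROI]
    selection: tuple[float, float, float, float]
    crop_fraction: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": list(self.area_fraction),
                "true_area_fraction": list(self.area_fraction.values()),
                "true_intensity_fraction": list(self.intensity_fraction.values()),
                "n_colonies": list(self.n_colonies.values()),
            }
        )


def _place_colonies(rng, centre, analysis_radius, mask_count, spec, shape):
    """Random sequential placement of non-overlapping colony discs.

    Returns (label grid, intensity grid, n_colonies).  Colonies lie fully
    inside the analysis disc so ground truth and measurement see the same
    pixel set.
    """
    labels = np.zeros(shape, dtype=bool)
    intensity = np.zeros(shape, dtype=np.uint8)
    cx, cy = centre
    covered = 0
    n_col = 0
    target_px = spec.target_coverage * mask_count
    r_lo, r_hi = spec.colony_radius_range
    failures = 0
    while covered < target_px:
        r = rng.uniform(r_lo, r_hi)
        max_off = analysis_radius - r
        if max_off <= 0:
            raise GenerationError("colony radius exceeds the analysis disc")
        rho = max_off * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        ccx, ccy = cx + rho * np.cos(phi), cy + rho * np.sin(phi)
        disc = _disc_mask(shape, (ccx, ccy), r)
        if (labels & disc).any():
            failures += 1
            if failures > 5000:
                raise GenerationError(
                    f"coverage {spec.target_coverage:.2f} unreachable: disc "
                    "placement jammed (reduce coverage or colony size)"
                )
            continue
        labels |= disc
        intensity[disc] = rng.integers(
            spec.colony_intensity_range[0], spec.colony_intensity_range[1] + 1
        )
        covered += int(disc.sum())
        n_col += 1
    return labels, intensity, n_col


def render_plate(
    layout: PlateLayout | str | int,
    dpi: float,
    specs: dict[str, SyntheticWellSpec] | SyntheticWellSpec,
    shading: float = 0.0,
    shading_start: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> tuple[PlateImage, SyntheticTruth]:
    """Render a full synthetic plate scan and its ground truth.

    The image spans exactly ``cols x pitch`` by ``rows x pitch`` at the
    given dpi, so the natural analysis selection is the full image.
    ``shading`` is the amplitude (intensity units) of a linear left-to-
    right darkening gradient; ``shading_start`` (fraction of the image
    width, default 0) is where the ramp begins, so a start of 0.5 leaves
    the left half uniformly lit — the typical look of a scan with one
    shaded side.  ``noise_sd`` adds i.i.d. Gaussian noise, rounded
    half-up and clipped to [0, 255].  Deterministic for a fixed seed.
    When ``noise_sd > 0`` the colony/background separation must exceed
    ``4 x noise_sd`` so that truth-exactness remains meaningful.
    """
    layout = get_layout(layout)
    px_per_mm = dpi / 25.4
    w = round(layout.cols * layout.well_pitch * px_per_mm)
    h = round(layout.rows * layout.well_pitch * px_per_mm)
    selection = (0.0, 0.0, float(w), float(h))
    grid = grid_from_selection(selection, layout)
    if isinstance(specs, SyntheticWellSpec):
        specs = {roi.well_id: specs for roi in grid}
    missing = [roi.well_id for roi in grid if roi.well_id not in specs]
    if missing:
        raise ValidationError(f"specs missing for wells {missing}")

    img = np.full((h, w), float(INTERWELL_INTENSITY))
    labels = np.zeros((h, w), dtype=bool)
    area_fr, int_fr, n_cols = {}, {}, {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(grid) + 1)
    for roi, child in zip(grid, child_seeds[:-1]):
        spec = specs[roi.well_id]
        if spec.target_coverage > MAX_COVERAGE:
            raise GenerationError(
                f"well {roi.well_id}: target coverage {spec.target_coverage:.2f} "
                f"exceeds the hard-disc placement limit {MAX_COVERAGE}"
            )
        if noise_sd > 0 and (
            spec.background_intensity - spec.colony_intensity_range[1]
        ) <= 4 * noise_sd:
            raise GenerationError(
                f"well {roi.well_id}: colony/background separation must exceed "
                "4 x noise_sd"
            )
        rng = np.random.default_rng(
            spec.seed if spec.seed is not None else child
        )
        well_disc = _disc_mask((h, w), roi.centre, roi.radius)
        img[well_disc] = spec.background_intensity
        analysis_radius = roi.radius * (1.0 - crop_fraction)
        analysis = _disc_mask((h, w), roi.centre, analysis_radius)
        mask_count = int(analysis.sum())
        well_labels, well_int, n = _place_colonies(
            rng, roi.centre, analysis_radius, mask_count, spec, (h, w)
        )
        img[well_labels] = well_int[well_labels]
        labels |= well_labels
        in_mask = well_labels & analysis
        area_fr[roi.well_id] = in_mask.sum() / mask_count
        int_fr[roi.well_id] = float(
            (255.0 - img[in_mask]).sum() / (255.0 * mask_count)
        )
        n_cols[roi.well_id] = n

    if shading:
        xs = np.arange(w, dtype=float) / max(w - 1, 1)
        ramp = np.clip((xs - shading_start) / max(1.0 - shading_start, 1e-9), 0, 1)
        img = img - shading * ramp[None, :]
    if noise_sd > 0:
        noise_rng = np.random.default_rng(child_seeds[-1])
        img = img + noise_rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    truth = SyntheticTruth(
        area_fraction=area_fr,
        intensity_fraction=int_fr,
        n_colonies=n_cols,
        labels=labels,
        grid=grid,
        selection=selection,
        crop_fraction=crop_fraction,
    )
    return PlateImage(img, dpi=dpi, source=f"synthetic(seed={seed})"), truth


def simulate_dose_response(
    model: DoseResponseModel,
    doses,
    replicates: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Response-level simulation of a replicated dose series.

    Responses are ``ll4(dose) + N(0, noise_sd)``, truncated to [0, 100]
    (percent scale).  Mirrors a quadruplicate-well plate design without
    rendering images.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValidationError("doses must be strictly positive")
    if replicates < 1:
        raise ValidationError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        base = float(ll4(dose, model))
        for rep in range(replicates):
            resp = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {"dose": dose, "replicate": rep + 1,
                 "response": float(np.clip(resp, 0.0, 100.0))}
            )
    return pd.DataFrame(rows)


def render_dose_response_plates(
    model: DoseResponseModel,
    doses,
    replicates: int,
    layout: PlateLayout | str | int = "24-well",
    dpi: float = 200.0,
    noise_sd: float = 0.0,
    shading: float = 0.0,
    seed: int = 0,
) -> tuple[PlateImage, SyntheticTruth, dict[str, float]]:
    """Image-level dose-response simulation on one plate.

    Wells are assigned row-major, ``replicates`` consecutive wells per
    dose; each well's target coverage is ``ll4(dose) / 100``, so the
    response the pipeline should recover traces the generating curve.
    The model's upper limit must keep coverage at or below the hard-disc
    placement cap (50%).

    Returns the plate, its truth, and the well -> dose map.
    """
    layout = get_layout(layout)
    doses = np.asarray(doses, dtype=float)
    n_needed = len(doses) * replicates
    if n_needed > layout.n_wells:
        raise ValidationError(
            f"{n_needed} wells needed but layout has {layout.n_wells}"
        )
    from .geometry import well_id as _wid

    ids = [_wid(r, c) for r in range(layout.rows) for c in range(layout.cols)]
    specs: dict[str, SyntheticWellSpec] = {}
    dose_map: dict[str, float] = {}
    for k, wid in enumerate(ids):
        if k < n_needed:
            dose = float(doses[k // replicates])
            coverage = float(ll4(dose, model)) / 100.0
            dose_map[wid] = dose
        else:
            coverage = 0.0
        specs[wid] = SyntheticWellSpec(target_coverage=max(coverage, 0.0))
    plate, truth = render_plate(
        layout, dpi, specs, shading=shading, noise_sd=noise_sd, seed=seed
    )
    return plate, truth, dose_map
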