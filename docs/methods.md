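# Methods

## Scope and model

`colonyquant` quantifies colony formation in multi-well plates from scanner
images by coverage statistics rather than colony counts. The underlying
assumptions are those of the standard crystal-violet workflow: stained
cells are darker than the background, illumination is approximately
uniform within a well, wells are circular and evenly spaced on a
rectangular plate, and the scan resolution (≥ 800 dpi recommended for real
plates) makes single wells several hundred pixels across.

## Geometry

Well centres come from arithmetic alone: a rectangle enclosing an r×c block
of wells is divided into a uniform lattice; the nominal well radius is
`(well_diameter / well_pitch) × (lattice span / 2)` using the smaller of
the x/y spans. Built-in layouts (6-well 34.8/39.12 mm, 12-well
22.1/26.01 mm, 24-well 15.6/19.3 mm; diameter/pitch) follow typical
CELLSTAR-style dimensions and are user-overridable. There is deliberately
no image-based circle detection: the selection rectangle is the ground
truth, which makes the pipeline deterministic and robust to plates with
sparse growth.

Disc membership uses the half-open rule `dx² + dy² < r²` at pixel centres
(origin top-left, x rightward, y downward). "Reduce the diameter by 5 %"
is implemented as one multiplication of the radius by 0.95 (not 5 % per
edge); the crop fraction is a parameter, so the alternative reading is one
flag away.

## Grey conversion and input handling

RGB scans are converted by the unweighted channel mean with half-up
rounding; Rec.601 luma is available via `method="rec601"`. 16-bit inputs
are min–max rescaled onto 0–255 as a convenience; the analysis itself is
defined on 8-bit data. The dpi is read from TIFF/PNG resolution metadata
and must be supplied explicitly when absent — geometry only needs it for
synthetic rendering, but it is part of the provenance record.

## Background threshold detection

For each well the curve `A(t)` (percentage of masked pixels with intensity
≤ t) is the cumulative histogram; its backward difference `dA` is the
percentage histogram, and `d2A` the difference of `dA` (`dA[0] = A[0]`,
so `Σ dA = 100` exactly). `dA` is smoothed with a centred moving average
of window 3 before extremum analysis; the raw curve is retained.

Two decisions had to be fixed where the underlying idea ("the valley below
the background surge") leaves freedom:

1. **Peak.** The background mode is the mode at *high* intensity, not
   necessarily the globally densest bin (densely stained colonies can
   concentrate more mass per bin than a wide background). The peak is the
   highest intensity whose smoothed density reaches ≥ 5 % of the global
   maximum (`peak_frac`).
2. **Valley.** The threshold is the highest intensity strictly below the
   peak that is a weak local minimum of the smoothed histogram *and* whose
   density is at most 10 % of the peak height (`rel_depth`). The depth
   condition skips the shallow wiggles a noisy histogram exhibits inside
   the background mode itself (a plain nearest-local-minimum descent stops
   at the first such wiggle); the highest-intensity rule keeps the cell
   call conservative with respect to the background, matching the
   transition-point reading: the last quiet point before the surge. When
   no minimum is deep enough (heavily overlapping modes), the global
   minimum below the peak is used, ties towards the peak.

"Below the threshold" is inclusive (`intensity ≤ t`), one convention
everywhere. A well whose curve carries no cell mass below the valley
(`A[valley] ≤ min_cell_area`, default 0) is reported `no_colonies` — a
result state, not an error; its statistics are 0. Thresholds equal to 255
are rejected (they would classify pure white as cells).

## Consistency check

Per-plate harmonisation: each threshold is rescaled by `200 / max
intensity` of its well (float, no rounding during comparison), the mean of
the scaled thresholds is taken, and wells deviating by more than the
tolerance (default 50 units) are re-thresholded with the search restricted
to the mean ± tolerance window mapped back to native intensities (half-up
rounding at this point only). The restricted re-detection re-runs the full
derivative analysis inside the window. Two choices:

- Wells reported `no_colonies` are excluded from the plate mean and never
  re-evaluated — their "threshold" (the top of the empty cumulative range)
  does not estimate a background valley and would skew the mean.
- The mean includes flagged wells; an iterated variant with exclusion was
  considered and rejected to keep the procedure single-pass and
  order-independent. On the worked example (scaled thresholds
  [100, 105, 180], tolerance 50) exactly the third well is flagged and a
  second pass changes nothing.

## Statistics

Both statistics are computed over the analysis mask intersected with the
optional sub-region rectangle — the denominator of the intensity statistic
is "all analysed pixels × 255" (full saturation), so the bounding square
and any pixels outside the circular mask never enter. Percentages are kept
at full float precision internally and in the CSV, so file round-trips are
bit-exact.

## Dose–response fitting

The LL.4 model `f(x) = c + (d−c)/(1 + exp(b(ln x − ln e)))` is fitted by
nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective) on raw replicate points, parameterised in `log e` on log-dose
for stability; the IC50 standard error is back-transformed by the delta
method (`SE(e) = e · SE(log e)`). Initialisation: `d₀` = max response,
`c₀` = min response, `e₀` = dose nearest the half-range crossing,
`b₀ = 1`; `e` is bounded to `[min dose/10, max dose×10]`. Zero-dose
controls are excluded (ln x undefined); `anchor_upper` optionally fixes
`d` at the control mean instead. A response vector with zero spread raises
a fit error (no dose effect). Within-fit standard errors come from the
estimated covariance; aggregation across biological repeats (SEM) is left
to the user, as the two uncertainty layers are distinct.

## Synthetic data

The generator renders what the pipeline consumes: light intra-well
background (default 220), inter-well plastic at mid-grey 140, colonies as
non-overlapping hard discs (radius 2–6 px at the default scale) with
per-colony uniform intensity 60–100, optional linear shading ramp
(amplitude plus a start fraction, so one side of the plate can stay
clean), and i.i.d. Gaussian noise rounded half-up and clipped to [0, 255].
Ground truth (covered fraction, intensity-weighted fraction, colony count,
label grid) is computed from the rendered raster inside the analysis mask,
never from the request, so exactness tests compare like with like.

Deliberate simplifications, and what they imply for test evidence:

- Hard-disc sequential placement jams near the random packing limit
  (~0.55), so target coverage is capped at 0.5 and requests above it raise
  a generation error; image-level dose-response simulations therefore use
  an upper plateau of 45 % coverage. Response-level simulations
  (no images) use the full 0–100 % scale.
- Colonies are sharp-edged uniform discs; real colonies have soft edges
  and radial density profiles. Passing exactness tests show the pipeline's
  bookkeeping (masks, thresholds, counts) is correct, not that threshold
  placement is optimal for diffuse real-world staining.
- Noise is i.i.d. Gaussian; scanner artefacts (unsharp-mask halos, JPEG
  blocks, dust) are out of scope. A separability guard (background −
  colony max > 4 × noise sd) keeps noisy renders within the regime where
  ground truth remains meaningful.

The shading scenario used in validation: one well at 25 % coverage with
colonies at 130–170 on background 240, and a ramp of amplitude 100
starting at mid-well. Full-well analysis then misclassifies the shaded
background as cells (the detected threshold separates only the clean
background), while reanalysis of the clean half recovers the true
coverage exactly — the intended use of the sub-region option.

## Problem sizes and determinism

Validation runs use 12/24-well plates rendered at 120–300 dpi (wells of
roughly 10⁴–5·10⁴ analysed pixels), 100-well threshold-oracle batches,
1000 random 9×9 density grids, and 200 Monte-Carlo dose-response
repetitions (quadruplicates at 8 doses, noise sd = 5 % of the upper
plateau) — sizes at which every property stabilises while the whole suite
runs in well under a minute. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give bit-identical
images and tables.

## Known limitations

- No rotation correction or automatic plate localisation: a skewed scan
  needs a skew-free selection rectangle.
- The threshold detector assumes a background mode brighter than the
  colonies; inverted stains (light cells on dark background) are not
  supported.
- Flat-field/illumination correction is intentionally absent; the remedy
  for shading is sub-region analysis plus the cross-well consistency
  check.
- One plate per image; multi-page TIFFs are not handled.
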