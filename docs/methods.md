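# Methods

## Wound-area measurement

Scratch images are single-channel fluorescence acquisitions of a
CellTracker- or phalloidin-stained monolayer at 2.97 μm/pixel, carrying a
nominally 0.38 × 3.8 mm rectangular wound (≈128 × 1280 px).  The pipeline:

1. **Smoothing** — median filter, window `smooth_kernel_px` (default 3 px;
   1 disables).
2. **Background flattening** — subtraction of a Gaussian-smoothed background
   estimate at scale `flatten_kernel_px`, re-centred on the image mean and
   clipped at zero.  *Default off.*  Any local background estimator treats
   the interior of a vast confluent monolayer as background and erases the
   bright/dark contrast the threshold step needs; flattening is therefore an
   opt-in step for data with genuine shading, which the synthetic images do
   not carry.
3. **Thresholding** — Otsu's method for light (cell-covered) objects.  Otsu
   is the standard parameter-free global threshold; the method slot is
   configurable.
4. **Dilation** — the cell mask is dilated by a square element of radius
   `dilation_px` = 4, equivalently the wound is eroded by 4 px on each side,
   so the measured wound never includes cell edges.
5. **Inversion and size filtering** — the complement of the dilated cell
   mask is labelled with 8-connectivity and components below the
   timepoint-specific minimum are removed: 10,000 px at t=0 (removes
   monolayer tears) and 100 px at 24 h (removes residual slivers; bright
   debris inside the wound is already part of the cell mask).  The summed
   surviving area is the measurement.

`Am = A0 − A24` is never clipped: a negative value records wound
enlargement.  On noise-free two-level images with smoothing disabled the
pipeline is *exact*: the measured area equals the brute-force pixel count of
the eroded wound rectangle ((h−8)(w−8) for an h×w wound).  With the default
3-px median filter the four wound-corner pixels flip to the majority
(cell) side, costing exactly 4 px — the filter exists for noisy images,
where end-to-end error stays well under 1%.

A constant (contrast-free) image cannot be thresholded; it yields area 0
with a warning rather than an exception, so a fully closed well does not
abort a plate.

**Scratch-failure gate.**  Wells whose measured A0 falls below a configurable
fraction of the nominal scratch area are flagged `failed_scratch` and
excluded from normalisation.  This is an automated surrogate for the manual
plate-view inspection used in production screens; it catches failed
scratches but not contamination or seeding faults.

**Sentinel plates.**  When a batch shares one t=0 plate, per-well-position A0
values are substituted into every plate of the batch, and the
coefficient of variation of sentinel A0 across pins is reported as batch QC.

## Nuclei counting and the viability gate

Nuclear-stain fields are thresholded (Otsu), labelled (8-connectivity) and
measured per object.  Valid nuclei have area in [60, 1400] px (inclusive by
default; the bounds' inclusivity is configurable because conventions differ)
and mean intensity strictly below the 12-bit saturation value 4,095.
Touching nuclei merge into one object — watershed splitting is deliberately
not implemented, and the synthetic fields place nuclei without contact, so
counts against truth are exact.  Otsu degenerates on unimodal images, so
object detection requires the foreground/background mean separation to span
at least half the image's dynamic range; below that the field is declared
object-free.

The per-well total over 30 fields is gated at 3,300 nuclei
(110 cells/field, just under 60% of the healthy median of 187.5
cells/field); totals below the gate bin the well *Low Cell Count*, and that
bin suppresses any migration bin for the well.  The parameter defaults are
cross-checked at construction (110 × 30 = 3,300) and can be overridden
explicitly.  When fewer than 30 fields are available the total can
optionally be rescaled; by default it is a plain sum.

## Screen statistics

- **Normalisation**: per physical plate (plate × technical replicate),
  `norm = Am / median(Am over usable mock wells)`; at least two usable mocks
  are required.  Non-targeting reference wells are recorded but excluded
  from normalisation and QC.
- **Robust z**: technical replicates are averaged first, then z is computed
  *screen-wide* across all library siRNAs.  Per-plate z over 80 library
  wells is unstable; the screen-wide form is the default and the
  normalisation already removes plate effects.  The MAD carries the 1.4826
  normal-consistency factor (configurable to 1).
- **Binning**: strict inequalities exactly as the thresholds are stated —
  primary z < −2 / z > 2; secondary normalised score < 0.6 / > 1.3;
  viability total < 3,300; SSMD pass at ≥ 1.  Every library siRNA receives
  exactly one of {LowCellCount, Inhibited, Accelerated, none}.
- **SSMD**: method-of-moments two-sample form with n−1 variances, oriented
  so an effective migration-reducing positive control scores positive; a
  median/MAD robust variant is available by flag.  Each physical plate is
  passed or failed on the better of its siCDC42 and siCDH5 SSMDs; failed
  plates are dropped with a logged reason and the surviving replicate
  carries the plate.
- **Deconvolution confidence**: a gene's four duplexes are binned on the
  secondary scale; confidence follows the count reproducing the original
  phenotype (0→none, 1→low, 2→medium, 3→high, 4→very high).  *Toxic*
  requires exactly one Low Cell Count duplex with the other three quiet.
  "Reproducing" is direction-only (an originally Inhibited gene reproduces
  via Impaired duplexes); no magnitude criterion is imposed.
- **Tertiary classes**: technical replicates are averaged, then biological
  replicates, then each gene is called impaired per cell type at the
  secondary threshold.  *Common* = impaired in both; *dominant* = impaired
  in exactly one cell type.  A margin-based dominance rule was considered
  and rejected as the default because exclusivity reproduces the published
  partition arithmetic without an extra free parameter.

## Morphometrics

Cells are segmented by marker-based watershed: nuclei (nuclear channel,
thresholded, specks under 25 px discarded) seed basins in the inverted
whole-cell channel restricted to its foreground.  Eleven features are
measured per cell on the F-actin channel, in fixed order: area, perimeter,
breadth, length, shape factor, elliptical form factor, texture difference
moment, inverse difference moment, average intensity, total intensity,
intensity s.d.

- *Length/breadth* are the maximum caliper (Feret) diameter and the maximum
  extent perpendicular to it, from the convex hull of pixel corners.
- *Perimeter* uses the Crofton estimator (4 directions): a digital disk's
  shape factor 4πA/P² then lands within 1% of 1, whereas naive pixel-edge
  counting overestimates P by ~11% and was rejected.
- *Texture moments* are grey-level co-occurrence statistics over in-mask
  pixel pairs, 32 quantisation levels, offset 1 px, symmetric, averaged
  over 4 directions: contrast Σp(i−j)² and homogeneity Σp/(1+(i−j)²).  A
  constant region gives 0 and 1 exactly.  The reference instrument's exact
  texture formulas are unpublished; these standard forms are declared
  substitutes, with bin count and offset as configuration.
- Cells touching the image border are measured but excluded from well
  aggregates.

Well signatures are per-feature means over valid cells; screen signatures
are replicate-averaged per siRNA and robust z-scored per feature
(median/MAD × 1.4826).  Plain mean/s.d. z-scoring is available by flag; the
robust form is the default because the deposited signature data are
described as robust z-scored.  A zero-MAD feature raises an error naming
the feature.

## Clustering

Signature rows are clustered with d = 1 − Pearson (range [0, 2]), complete
linkage, dendrogram cut at height 1.5, clusters numbered by left-to-right
leaf order.  Quantile binning is provided for heatmap export only;
clustering always uses the unbinned z-scores — whether the original
web-service clustering consumed binned values is ambiguous, and unbinned
clustering is the conservative reading.  Cross-cell-type comparison reports
the per-gene Pearson r between the two 11-vectors and its distribution
summary.

## Synthetic data

The generators define the study conditions for all tests:

- **Wound pairs**: monolayer texture is clipped Gaussian-blurred speckle
  above a dark background (foreground 2000, background 200, `noise_sd`
  40 by default, 0 for the exact regime) — downstream thresholding needs
  contrast, not realism.  The wound closes symmetrically from both long
  edges, so truth areas are exact integers.  Debris specks are ≤ 50 px each
  (must be absorbed by the cell mask / A24 filter); tears are 100–9,999 px
  (must be removed by the A0 10,000-px filter but would survive the A24
  filter) — deliberately exercising the asymmetric size filters.
- **Nuclei fields**: non-overlapping ellipses with areas in (100, 400) px,
  aspect ≤ 1.6, intensity ≈ 3000 ± 15% (below the 4,095 gate); the healthy
  field density is 187 cells/field.  Rejection placement raises a capacity
  error when the requested count cannot fit.
- **Cell fields**: registered nuclear / whole-cell / F-actin channels; each
  cell an ellipse with a concentric nucleus at 35% of its axes; F-actin
  carries the truth mean intensity with controllable within-cell variance.
- **Plates**: effects are multiplicative on the mock-normalised migration
  scale with additive Gaussian noise — the simplest model consistent with
  mock-median normalisation.  Defaults: inhibitors ×0.5 (5%), accelerators
  ×1.5 (5%), lethal 2% with cell counts ×0.3 and impaired migration (so the
  viability gate's precedence is exercised), well noise s.d. 0.1 shared
  between the replicates (both derive from one transfection mix), replicate
  noise s.d. 0.05.  With these defaults the simulated replicate correlation
  (median r ≈ 0.94) and plate SSMDs (≈3–6) sit in the range reported for
  production screens of this design.  Positive controls: siCDC42 ×0.35,
  siCDH5 ×0.5; the non-targeting reference is mildly accelerated (×1.15)
  and excluded from analysis.  Randomness derives from one root seed with
  per-plate child streams keyed by (seed, plate index), so any subset of
  plates reproduces exactly.  The true effect-size distribution of real
  screen hits is unknown; these values are declared conditions, not
  estimates.

What the generators do **not** emulate: optical shading and flat-field
artefacts, montage stitching seams, cell-shape realism, touching nuclei,
transfection biology, or spatial (edge) effects within plates.  Passing
tests therefore demonstrate the correctness of the measurement and
statistics chain under the stated noise model, not robustness to every
artefact of production imaging.

## Problem sizes

Tests and the acceptance script use desk-scale versions of each stage,
chosen as the smallest sizes at which every statistic is informative:
wound images 384 × 1536 px with the full-size 128 × 1280 px scratch;
nuclei fields 768 × 768 px at the median density; a 10-plate primary screen
(800 library siRNAs); 60–120 deconvolution genes; ~80 tertiary genes; and a
10-siRNA morphology screen with 5 cells per 360 × 360 px field.

## Known limitations

- The wound pipeline assumes pre-stitched single images and a roughly
  axis-aligned rectangular scratch; it measures area only (no per-cell
  tracking or velocity).
- Touching nuclei under-count; the viability gate tolerates this in
  practice because it is a coarse 60%-of-median threshold.
- No spatial (B-score/loess) correction and no FDR control: hit calling
  uses the fixed thresholds of the original design.
- The exact smoothing/flattening kernels of the reference acquisition
  software are unpublished; kernel sizes are configuration, and the chosen
  defaults are validated only against the synthetic truth.
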