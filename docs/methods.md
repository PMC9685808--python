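# Methods

## Fluorescence model

A dark-adapted fluorescence acquisition yields two frames in 12-bit digital
numbers (DN, 0–4095): the minimum fluorescence F0 under weak measuring light
and the maximum Fm under a saturating pulse. The derived map
Fv/Fm = (Fm − F0)/Fm quantifies the maximum quantum efficiency of
photosystem II; it is ≈ 0.83 in unstressed tissue and decreases under biotic
stress before visible symptoms appear. Pixels with Fm = 0 (non-fluorescing
background) are assigned Fv/Fm = 0 and counted.

Per tissue class we model the two frames as independent per-pixel Gaussians,
summarized by `FluorParams = (μF0, σF0, μFm, σFm)`. This ignores within-leaf
spatial autocorrelation and the F0–Fm correlation at a pixel; both are
deliberate simplifications — the target application (training a lesion
segmenter) needs the correct marginal contrast between tissue classes, not a
physically complete image-formation model. Statistics are estimated with the
sample (n−1) denominator, since the packaged tables are themselves empirical
estimates. The empirical ordering μF0 < μFm holds in every packaged row;
`FluorParams` warns (rather than errors) when user data violate it.

## Disease shifts

Disease raises F0 statistics and lowers Fm statistics. The four relative
shifts are defined with signs that make symptomatic values positive:

    ΔμF0 = (μF0(d) − μF0(h)) / μF0(h)       ΔμFm = (μFm(h) − μFm(d)) / μFm(h)

(σ analogous). Diseased parameters are re-synthesized from healthy ones by
`μF0(r) = μF0(1 + ΔμF0)`, `μFm(r) = μFm(1 − ΔμFm)`, with each Δ drawn
independently and **uniformly** from its [min, max] range — the minimal
assumption given only range information; the distribution is a config option
(`delta_distribution`). `compute_deltas` and `apply_deltas` are exact
inverses, which the tests exploit as a round-trip property.

The packaged ranges (`table3_ranges.csv`) are used verbatim for synthesis.
They are *not* exactly the componentwise envelope of the packaged per-day
healthy/diseased table: the published ranges were evidently estimated at a
finer grouping (per dish) that the per-day table averages over. The per-day
envelope over the symptomatic days 2–8 does reproduce the σF0 minimum (0.27
at two decimals), and that is the component the acceptance script checks. Day
0 is excluded from range estimation by default because its shifts are
negative (pre-symptomatic), while the sampling ranges are non-negative.

## Noise-field synthesis

A tissue patch is `x = 1 − a/b` with `a ~ N(μF0, σF0²)`, `b ~ N(μFm, σFm²)`
i.i.d. per pixel. The raw ratio is unbounded: `b` can approach 0 and `a` can
exceed `b`. Two guards keep the field physical:

- denominator draws below `b_floor_frac·μFm` (default 0.05) are redrawn —
  a division guard affecting ~10⁻⁴ of draws at the packaged parameter values;
- the assembled field is clipped to [0, 1], the physical range of a quantum
  efficiency.

Both are config-exposed. With σ = 0 the field degenerates to the constant
1 − μF0/μFm (used as a noiseless test limit).

Per plant, leaves are iterated in label order. Each leaf draws its own
healthy day row (uniform over the packaged table; `healthy_sampling:
per_plant` shares one row across the plant, `fixed_day` pins it) and its own
diseased parameter draw, so one plant carries lesion-contrast heterogeneity.
All four statistics of the chosen row are used jointly for both numerator and
denominator fields. Later leaves overwrite earlier ones where they overlap —
image values *and* lesion annotation — so the diseased class of the final
mask is exactly the union of the effective per-leaf lesion masks: annotation
noise is zero by construction, which is the point of the generator. The
background is set to Fv/Fm = 0, matching dark non-fluorescing background in
fluorescence imagers.

## Lesion speckle

Early bacterial lesions appear as many tiny scattered blobs. We generate them
as a thresholded correlated Gaussian field — the standard statistical
surrogate for fully developed speckle: i.i.d. Gaussian noise, Gaussian
low-pass with σ = `correlation_length` (default 2 px, setting the blob
scale), thresholded at the within-leaf quantile giving `coverage_target`
(default 0.05, so realized coverage tracks the target closely for leaves of a
few hundred pixels). A leaf carries lesions with `lesion_probability`
(default 0.8). `coverage_target ≥ 1` is accepted as a degenerate hook for a
fully diseased leaf. With the default rosette distribution these choices put
the generated severity in the sub-percent early-infection regime (mean
≈ 0.6 %, max ≈ 2 % over 200 plants), bracketing the empirical severity scale
the generator is meant to emulate.

Morphological cleanup for empirical test sets removes 8-connected components
below `min_object_px` (default 4) and closes the remainder with a disk of
`closing_radius` (default 1) to fill pinholes; disk and 8-connectivity were
chosen for isotropy, and the operation is idempotent.

## Procedural rosettes

Hand-labelled rosette imagery is emulated by a parametric generator: ovate
leaf lobes (half-width profile `t^0.5 (1−t)^0.3` along the axis, petiole at
the center) placed at golden-angle (137.5°) phyllotaxis with jittered
orientation, length and center; later leaves overwrite earlier ones, as in
occluded top views. `sample_rosette_spec` draws 2–16 leaves and a global
scale such that plant sizes span < 2 % to > 40 % of a 128×128 canvas, the
range seen in top-view rosette datasets. The shapes carry no venation,
serration or growth model: the synthesis only needs blob-like silhouettes,
and passing tests on procedural shapes says nothing about leaf-shape realism
— only about the fluorescence statistics painted onto them.

## Preprocessing and augmentation

Four-plant 512×512 frames are split into quadrants (TL, TR, BL, BR) and
resized to 128×128 — bilinear for intensities, nearest-neighbor for labels so
class codes survive. Severity filtering keeps records with S strictly above
the threshold (default 0.24 %). Augmentation selects ⌊fraction·n⌋ distinct
samples after a seeded shuffle (defaults fraction 0.7, seed 42) and appends
exactly one copy per selection, transformed by one of {horizontal flip,
vertical flip, 90° rotation} applied identically to image and mask; the count
contract n + ⌊fraction·n⌋ gives 9317 from 5481. Severity and plant size are
exact count ratios, hence invariant under all three transforms.

## Evaluation

Only the diseased class is scored: TP/FP/FN pixel counts give recall
TP/(TP+FN), precision TP/(TP+FP) and F1 = TP/(TP+0.5(FP+FN)) (the harmonic
mean of the former two). Undefined ratios (zero denominators) are reported as
NaN, not 0, so dataset aggregates can exclude degenerate images; aggregates
are reported both micro (pooled counts) and macro (mean of per-image scores)
since the two differ under skewed severity. The smoothed dice overlap
D = (2Σyy* + ε)/(Σy + Σy* + ε), ε = 0.001, is exposed both as the coefficient
and as the loss 1 − D.

## Problem sizes and determinism

Tests and the acceptance script run the generator at its native 128×128
resolution with ensembles of 100–500 plants/seeds and up to 10⁷-draw
Monte-Carlo oracles; these sizes give standard errors far below the asserted
3-sigma tolerances while completing in well under a minute each. Every random
path flows through a `numpy.random.Generator`; dataset builds derive one
recorded integer seed per sample from the master seed, so any sample can be
regenerated alone and full rebuilds are bit-exact.

## Known limitations

- No spatial correlation or F0–Fm coupling within a tissue class; empirical
  Fv/Fm histograms are wider and overlap more between classes than real ones.
- Single time point per sample: no lesion growth kinetics or day-to-day
  trajectory.
- The raw F0/Fm frame pair is not simulated for synthetic plants — only the
  derived Fv/Fm map, which is what segmentation consumes.
- No acquisition optics (vignetting, PSF, 3-D leaf pose) and no photometric
  augmentation; augmentation is restricted to the three geometric transforms.
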