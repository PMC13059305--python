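# Methods

`octaquant` re-implements, as a tested and reusable pipeline, the
quantitative machinery of a two-visit OCT-angiography (OCTA) study of
diabetic-retinopathy (DR) progression: en-face vessel metrics, foveal
avascular zone (FAZ) morphometry, choriocapillaris (CC) flow-deficit
analysis, outcome definitions on the ETDRS step scale, and a ladder of
logistic prediction models scored by AUC, Brier score and Hosmer–Lemeshow
calibration.  Because no patient images or tables are distributed with such
studies, a synthetic-data module generates both slab images with exact
pixel-level ground truth and eye-level cohorts with the statistical
structure the analysis assumes.  This note records the models, the
parameters that matter, and the design decisions taken where the published
description leaves latitude.

## Image model and vessel segmentation

An en-face slab is a 2D scalar grid in [0, 1] with an isotropic pixel pitch
(default 5.859 µm/px: a 3 × 3 mm field over 512 px).  Retinal slabs show
bright vessels on a dark background (decorrelation convention); the CC slab
is a bright background with dark flow voids.

Vessel enhancement combines two complementary ridge detectors:

- an **even-symmetric Gabor bank**, 8 orientations 22.5° apart, with
  wavelengths set to twice the expected vessel widths (capillaries ≈ 18 µm,
  arterioles/venules ≈ 45 µm at the native scale).  Kernels are zero-mean so
  flat regions respond zero; convolution is FFT-based on reflect-padded
  images to avoid border artifacts;
- a **multi-scale Hessian (Frangi) vesselness** at σ ∈ {1, 2, 4, 8} px.

Each detector's response is normalized to [0, 1] per scale by robust
(99th-percentile) scaling — per-scale normalization keeps the weak response
of thin capillaries from being swamped by large-vessel ridges — and the two
are combined by pixelwise maximum.  A square-root gamma is applied to the
combined map before thresholding: it compresses the bright large-vessel tail
of the histogram so that a single global threshold retains capillary recall.
The default binarization is global Otsu on the vesselness histogram; a local
mean − k·SD sliding-window alternative is selectable.  A constant input
yields an empty mask plus a warning, since no threshold separates classes.

**Large-vessel/capillary split.** Local caliber is measured as twice the
Euclidean distance transform at the medial axis and propagated to every mask
pixel from its nearest centerline pixel.  Pixels with caliber ≥ 30 µm
(inclusive; configurable) form the large-vessel (LV) mask.  Because
capillary junctions can momentarily exceed the cutoff, 8-connected LV
regions smaller than 8,000 µm² are reassigned to the capillary compartment:
an arteriole or venule crossing a 3 mm field is three orders of magnitude
larger than a junction blob, so the rule is insensitive to its exact value.
The LV and capillary masks partition the whole mask exactly, by
construction.

**Skeleton and length.** Masks are thinned to one-pixel centerlines
(topology-preserving Zhang thinning).  Centerline length is summed over
8-connected steps — axial steps count one pixel pitch, diagonal steps √2
of it — and attributed to pixels as *half-edge weights*: each pixel carries
half the length of its incident steps.  Summing the attribution map over
any pixel partition therefore splits the total length exactly, which is
what makes regional vessel density additive across the LV/capillary split.
Thinning erodes the ends of a bar by roughly two pixels, so recovered
lengths of finite segments are biased short by ~2 px per free end; closed
loops have no such bias.

## FAZ morphometry and regional densities

FAZ area is pixel count × pixel area.  Perimeter is measured on the
sub-pixel 0.5-level (marching-squares) contour after a 5-vertex circular
moving average of the contour coordinates: the raw staircase polygon
overstates a smooth boundary's length by ≈ 5%, which would bias circularity
by ≈ 10%; after smoothing, rasterized discs of radius ≥ 50 px measure
within 0.5% of 2πr.  Boundary-pixel counting (up to 27% high) is never
used.

Circularity is reported under two conventions: **literal** 4πA/P², bounded
above by 1 by the isoperimetric inequality and equal to 1 for a disc, and
**inverse** P²/(4πA), bounded below by 1.  Clinical tables sometimes print
values above 1, which are only consistent with the inverse convention; both
are first-class and the convention is recorded on the result.  The default
is literal.

Perfusion density (PD) is 100 × (vessel pixels in region)/(region pixels);
vessel density (VD) is skeleton length in the region (mm) per region area
(mm²).  The analysis region is the field minus the FAZ by default; a
concentric ring of configurable outer radius (measured from the field
center) is available, since published descriptions of the ring's outer
radius vary.  The FAZ delineation is an input (clinically it is drawn
manually); for synthetic slabs the generator's truth mask — or a flood fill
of the central avascular region — stands in.

## Choriocapillaris flow deficits

The CC slab is binarized at a global threshold of mean − 1·SD (k
configurable) computed over analyzable pixels; a pixel is a flow deficit
when strictly below the threshold, so a uniform image has no deficits.
Pixels under the exclusion mask — by default the superficial large-vessel
mask, to remove LV shadow artifact — contribute to neither numerator nor
denominator.  Components use 8-connectivity (fixed as the contract; 4- vs
8-connectivity changes component counts).  Besides the overall deficit
percentage, densities are reported counting only components strictly larger
than 200, 400, 600 and 800 µm², which makes the sequence of densities
non-increasing on every input.  No minimum-size speckle filter is applied
to the unthresholded density.

## Outcome definitions

ETDRS photographic severity levels are collapsed to steps
{10→1, 15→2, 20→2, 35→3, 43→4, 47→5}; levels outside this set raise an
error rather than extrapolate (the modelled cohort has no severity above
moderate non-proliferative DR).  DR progression is a step increase ≥ 2
between baseline and follow-up.  VA decline is a worsening of strictly more
than one line, with one line = 0.1 logMAR (ETDRS chart convention; the
tie at exactly 0.1 is not a decline).  Rows with incomplete visit data are
dropped with a logged count.

## Risk models

Two eyes of one patient are correlated, so no analysis treats eyes as
independent:

- **Group comparisons** use a marginal (GEE) model of the variable on group
  with an exchangeable working correlation clustered on patient.  Two
  standard small-sample corrections are applied: the bias-reduced
  (Mancl–DeRouen) sandwich covariance and a t reference with
  (clusters − parameters) degrees of freedom.  With these, the empirical
  type-I error at α = 0.05 on ~192-patient null cohorts is ≈ 5%; the
  uncorrected robust z-test runs ≈ 7–8% at this cluster count.  Continuous
  variables use an identity link, binary ones a logit; multi-level
  categoricals are tested by a joint Wald test with the model direction
  flipped (group on category dummies).
- **Adjusted odds ratios** come from logistic regression with
  cluster-robust (sandwich) variance on patient id, 95% Wald intervals.
  Complete separation is detected (coefficient magnitude, non-finite
  standard errors) and raised as an error, never silently reported.
  DR severity enters as a numeric 0/1/2 score (none / mild / moderate),
  i.e. linear in category.
- **Scoring**: AUC is the Mann–Whitney pairwise concordance (ties ½);
  Brier score the mean squared error of predicted probabilities;
  Hosmer–Lemeshow bins observations by deciles of predicted probability
  (ties kept together), statistic Σ (O−E)²/(E(1−E/n)), χ² reference with
  bins − 2 degrees of freedom.  All three are computed in-sample on the
  fitted cohort by default, matching the apparent (non-cross-validated)
  evaluation practice of the studies this mirrors; a grouped 5-fold
  cross-validation switch exists but is off by default.
- **Model ladders**: preset nested models for DR progression (established
  systemic factors; cohort-proposed factors; plus FAZ perimeter and/or
  superficial large-vessel VD) and for VA decline (systemic base plus
  superficial LV perfusion/vessel density).  No multiple-testing correction
  is applied by default, mirroring field practice; a Benjamini–Hochberg
  helper is deliberately not bolted on to the default report.

## Synthetic data

**Retinal slabs.** Large vessels are constant-width tubes (caliber drawn
uniformly from 30–60 µm) along smooth sinusoidally-perturbed chords that
avoid the fovea; the capillary bed is a jittered Voronoi mesh.  For a
Poisson point process of intensity λ, Voronoi edge length per unit area is
2√λ, so λ is chosen to hit the target capillary coverage (default 20% of
the field at 15 µm drawn width — chosen so that ground-truth superficial
PD falls in the clinically typical 20–30% range and VD in 15–22 mm⁻¹).
The FAZ boundary is an ellipse (default semi-axes 0.36 × 0.31 mm, area
≈ 0.35 mm²) with a low-order sinusoidal radial perturbation, so area,
perimeter and circularity are independently controllable; its area and
perimeter are computed from the parametric boundary by dense quadrature and
returned as ground truth.  Intensities: dark background (0.12), bright
capillaries (0.58) and large vessels (0.88) with multiplicative texture, a
slowly varying illumination field, a 0.7 px point-spread blur, and additive
Gaussian noise (SD 0.05).  Everything is drawn from one seeded generator;
identical parameters and seed give bit-identical images and truth.

**CC slabs.** Background N(0.62, 0.07²) clipped to [0, 1]; flow voids are
compact, slightly irregular dark components whose pixel areas match the
requested areas exactly, placed largest-first with a one-pixel moat so
components never merge; placement failures raise after a retry budget.
The default void list draws lognormal sizes (mean 450 µm², σ_log 1.2)
until 17% of the field is covered — parameters chosen so that deficit
density, mean void size, void count and the size-threshold density profile
land on clinically typical values.

**Cohorts.** 192 patients contribute one or two eyes (P(2 eyes) = 0.609,
expected 309 eyes).  Systemic covariates and eye-level OCTA metrics are
drawn on clinically realistic scales with a shared patient-level component
(≈ 60/40 between/within-patient variance split).  Outcomes follow
logit(p) = intercept + β·(x − x̄) + b_patient with b ~ N(0, 0.8²) shared by
fellow eyes — the structure a GEE or cluster-robust analysis must absorb.
The intercept is calibrated by Gauss–Hermite quadrature over the random
effect so the marginal prevalence hits its target (15.9% DR progression,
13% VA decline) regardless of the slopes.  Default slopes put a strong
effect on superficial large-vessel VD (OR 2.878 per mm⁻¹) and FAZ perimeter
(OR 1.583 per mm) with weaker systemic effects.  Follow-up ETDRS levels and
acuities are then constructed to be exactly consistent with the drawn
outcomes.  Severity categories map to baseline levels 10/20/35 (steps
1/2/3): clinically, mild and moderate NPDR sit at levels 35/43, but a
two-step worsening from level 43 has no representable follow-up level on
the collapsed step scale, so the simulator uses the lower representative
levels to keep every simulated progression expressible.  The
eyes-per-patient distribution is an explicit parameter, not an assertion
about any real cohort.

## What the synthetic data does and does not establish

The generator reproduces the *geometry and statistics the measurements
assume* — tube-like bright vessels, a single dark FAZ, noisy CC background
with compact voids, clustered binary outcomes — not OCT physics.  It omits
projection artifacts, motion/banding artifacts, signal-strength gradients,
segmentation (slab-placement) errors and vessel-caliber heterogeneity along
a vessel.  Passing tests therefore demonstrate that the measurement and
modelling machinery is correct on data satisfying its stated assumptions;
they do not certify accuracy on clinical scans, where artifact handling
dominates.  Parameter-recovery results (odds-ratio coverage) are likewise
statements about a correctly specified simulation: with a nonzero patient
random effect the marginal odds ratio estimated by cluster-robust logistic
regression is attenuated relative to the conditional (random-effect-scale)
coefficient, so the recovery study runs with the random effect off.

## Numerical choices and degenerate inputs

- Thresholds at exact ties: caliber cutoff is inclusive (≥); CC deficit
  threshold and void size thresholds are strict (< and > respectively);
  VA decline is strict with a 10⁻⁹ tolerance on the 0.1 logMAR tie.
- Problem sizes: the validation suite uses 100 slabs at 160 px for the
  partition invariants, 10 default-parameter 512 px slabs for segmentation
  recovery, 1,000 replicates for the null-calibration studies and 200 for
  parameter recovery; the acceptance script scales the replicate counts
  down (they are point estimates of the same quantities).
- Empty masks: skeletonization and density of empty inputs return zeros;
  empty FAZ or multi-component FAZ masks, empty regions, all-excluded CC
  fields and single-class outcomes raise errors.
- Derived seeds are kept below 2³¹.

## Known limitations

- No artery/vein differentiation within the large-vessel compartment.
- No projection-artifact removal for the deep plexus; deep-slab metrics use
  the same machinery as the superficial slab.
- FAZ segmentation from clinical images is out of scope (masks are inputs);
  only a flood-fill helper for synthetic slabs is provided.
- The per-model ancillary p-value column printed in some published ladder
  tables is ambiguous and is not reproduced.
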