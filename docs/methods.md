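# Methods

## Minkowski functionals on the pixel lattice

Foreground pixels are closed unit squares. The package counts the faces
(`F`), distinct covered unit edges (`E`) and distinct covered lattice
vertices (`V`) of their union and applies

* area `A = F`,
* perimeter `U = -4F + 2E`,
* Euler characteristic / genus `X = F - E + V`.

`U` equals the number of boundary edges because each pixel contributes four
edge incidences and interior edges absorb two each (`4F = 2·interior +
boundary`, `E = interior + boundary`). `X` is the Euler characteristic of the
closed cover: faces − edges + vertices. The closed-square convention fixes
the topology — foreground components are 8-connected (diagonal contact shares
a vertex), holes are 4-connected — and the two independent oracles in
`mfsurv.minkowski` (`boundary_edge_oracle`, `euler_oracle`) implement exactly
those definitions by differencing and flood fill, so the property tests check
the formulas against a genuinely different computation.

All three functionals are exact integers in pixel/edge units; no physical
pixel spacing is applied, since the features are used as unitless texture
descriptors. Empty and full masks are valid inputs, not errors.

A note on terminology: the radiological texture literature sometimes
describes `E` and `V` loosely as counts of "noncommunicating" pixels and
vertices. Taken literally (isolated pixels) that reading is inconsistent with
the standard worked example (8 pixels, 23 edges, 16 vertices → A=8, U=14,
X=1), which the cell-complex counting reproduces exactly; the package
therefore follows the counts, not the phrase.

## Threshold sweep

Normalization: optional division by the mean intensity of a disjoint
reference region (normal-appearing parenchyma), then min–max rescaling over
the ROI to [0, 1]. Min–max guarantees the sweep spans the ROI's dynamic
range: the first binary image is the full ROI and the last is empty. A
constant-intensity ROI maps to all zeros — only the threshold-0 image is
nonempty — and is treated as a documented degenerate case rather than an
error. The feature vector is invariant to affine rescaling of the raw
intensities (gain/offset are absorbed).

Binarization keeps pixels with normalized intensity strictly greater than
the threshold; the endpoint images at `t = 0` (whole ROI) and `t = 1`
(empty) are set by convention. Eleven equally spaced levels are the default
(`L` is configurable); prior texture work found no benefit beyond 11.
Because thresholding is nested, the area curve is non-increasing in the
threshold index for every input.

Multi-slice ROIs: the cell-complex counts are accumulated across slices
before applying the formulas. Slices are disjoint, so by additivity this
equals the sum of per-slice functionals and keeps one 33-vector per subject.
Whether to sum across slices or analyze one representative slice is a
genuinely open design point for this kind of pipeline; summing was chosen as
the convention here because it uses every segmented voxel and requires no
slice-selection rule.

## Survival analysis

* **Cox fits** maximize the partial likelihood with Efron's correction for
  tied event times (ties matter at day resolution); Wald 95% CIs per
  covariate, and a likelihood-ratio test against the null model for
  whole-model significance. Implemented via lifelines.
* **Ridge guard**: when the covariate count reaches one fifth of the event
  count, an unpenalized Newton iteration is fragile; the fit then uses a
  fixed small L2 penalty (0.1), recorded in the fit metadata. Texture
  features are z-scored by training-set statistics before entering any fit
  (33 correlated counts at heterogeneous scales otherwise destabilize the
  iterations), so texture hazard ratios are per SD.
* **Backward elimination** greedily drops the covariate whose removal lowers
  AIC (`-2 logPL + 2k`) the most and stops when no removal lowers it; ties
  are broken by dropping the covariate latest in declared column order, which
  makes the procedure deterministic. With pure-noise covariates it may reach
  the empty model. With the ridge guard active, AIC uses the partial
  log-likelihood evaluated at the penalized estimate.
* **Concordance** is Harrell's C over censoring-comparable pairs, score ties
  credited 0.5 (scikit-survival's censored concordance).
* **Split**: the test arm receives `floor(n·(1−ratio))` subjects allocated
  across the two event strata by largest remainder, so survival status stays
  balanced between arms up to one subject per stratum; reproducible under a
  seed. 113 subjects at 7:3 give 80/33.
* **Prediction error**: IPCW Brier score with censoring weights from the
  Kaplan–Meier estimate of the censoring distribution on the training arm;
  integrated Brier score by the trapezoidal rule over the unique test-arm
  event times below the shorter arm's maximum follow-up, divided by the grid
  span. Test subjects still at risk past the last evaluation time enter the
  score only through the at-risk indicator, so their follow-up times are
  truncated into the training range before weighting — an identity, not an
  approximation. The covariate-free training Kaplan–Meier is always reported
  as the reference model.
* **Clinical model composition** in the full workflow: univariately
  significant clinical covariates (α = 0.05) plus MGMT methylation status
  regardless of its p-value, since it is an established prognostic marker
  that a prognostic model for glioblastoma should carry.

## Synthetic cohort generator

The generator exists so that every stage has ground truth. Per subject:

* **Texture**: white noise convolved with a Gaussian kernel
  (`correlation_length` = kernel sigma in pixels, drawn per subject from
  1.2–3.5 px), scaled to unit variance inside the ROI, added with weight
  `amplitude` (default 1.0) to a smooth radial base profile, shifted
  non-negative. The ROI is an ellipse with low-order angular boundary
  perturbation, on a 48×48 grid by default. Gaussian random fields are the
  textures whose Minkowski functionals are analytically best understood,
  which makes the roughness knobs interpretable: shorter correlation length
  and larger amplitude both fragment the mid-threshold binary images
  (checked by Monte-Carlo tests).
* **Clinical covariates**: age ≈ N(58, 11) clipped to 25–78, male fraction
  0.58, MGMT methylated 0.55, non-total resection 0.49 — the demographics of
  a typical pre-operative glioblastoma cohort.
* **Survival**: log-hazard `β·x` over encoded clinical covariates and
  cohort-standardized texture features; defaults place clinical effects at
  the univariate scale typical for such cohorts (log HR 0.02 per year of
  age, 0.57 for non-total resection, −0.37 for methylated MGMT, 0 for sex)
  and texture signal on `A1`, `G2`, `G5` with per-SD log-hazards 0.2, 0.3
  and 0.45 — the feature subset and effect ordering mirror which features
  tend to matter (mid-threshold genus strongest), with magnitudes chosen
  once as moderate, detectable-at-n≈100 effects. Baseline is exponential
  (Weibull optional) with median 433 days; independent exponential censoring
  is calibrated by root finding so the expected censored fraction hits the
  target (default 0.17) jointly with an administrative cutoff at 2213 days,
  and a warning reports the achieved fraction when the target is missed by
  more than 10 points (expected for very small cohorts). Times are rounded
  to whole days (minimum 1), producing realistic ties. All randomness
  descends from one integer seed through per-subject `SeedSequence`
  substreams.

What the generator does **not** emulate: MR physics (bias fields, noise
correlations across slices, partial voluming), anatomy, scanner/protocol
heterogeneity, informative censoring, or any dependence between texture and
clinical covariates. Passing tests therefore demonstrate that the pipeline
is correct and that the statistics behave as designed under the
proportional-hazards model — not that texture features carry signal in any
particular clinical dataset.

## Problem sizes and numerical choices

Simulation-based tests use cohort sizes of 100–1000 subjects on 32×32 grids,
2000 observations for point recovery of a Cox coefficient, 200 replicates
for CI coverage, and 50 replicates for the model-ordering comparison; these
sizes give Monte-Carlo error comfortably inside the asserted tolerances.
AIC comparisons use a 1e-9 slack so bitwise-equal refits do not flip
decisions. Coverage assertions use the band [0.89, 0.99] around the nominal
0.95, about ±3 binomial standard errors at 200 replicates.

## Known limitations

* Perimeter is measured in lattice edges, which overestimates Euclidean
  boundary length of smooth shapes (no marching-squares sub-pixel boundary);
  consistent across subjects, so irrelevant for relative texture features.
* 3D Minkowski functionals and anisotropic pixel spacing are out of scope;
  slice stacks are treated as 2D slices summed.
* The backward elimination is greedy; it is the standard stepwise AIC
  procedure, not best-subset selection, and its selected set is
  cohort-specific.
* The IPCW Brier score assumes censoring independent of covariates
  (marginal Kaplan–Meier censoring model).
* DICOM ingestion, semi-automatic segmentation and image registration are
  out of scope; images enter as PNG/TIFF rasters or NIfTI volumes with
  same-shape binary masks.
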