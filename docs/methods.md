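# Methods

This note documents the models, conventions and numerical choices behind
`statomorph`: what each stage computes, why the defaults are what they are,
and what the synthetic data generator does and does not emulate.

## The analysis

A study consists of binary silhouette images of statoliths — the single
calcium-sulphate hard part found in each sensory rhopalium of a box
jellyfish — photographed in three orthogonal orientations (proximal, oral
and lateral faces, defined by the position of the crystal cleavage plane).
The pipeline runs:

1. **Silhouette → mask.** Fixed-threshold binarization (default 0.5 of the
   intensity range; inputs are near-binary), largest 8-connected component,
   interior holes filled. Component selection and hole filling are the
   programmatic analogue of manually erasing membrane fragments and dust
   from a silhouette photograph. Foreground touching the image border is an
   error, because a clipped outline is meaningless.
2. **Mask → outline.** Moore-neighbour boundary tracing with
   8-connectivity over pixel centres, scaled to micrometres by the
   manifest's `um_per_px`, y flipped so counterclockwise means positive
   signed area. Sub-pixel contouring is deliberately not used; the outline
   is a list of pixel coordinates.
3. **Traditional morphometrics.** Length = maximum Feret (caliper)
   diameter; width = maximum extent perpendicular to the length axis; the
   L:W ratio is compared among species with one-way ANOVA and Tukey–Kramer
   post-hoc tests per face. Both definitions are rotation-invariant, so the
   measurement does not depend on how the statolith was oriented on the
   slide.
4. **Elliptical Fourier analysis.** The outline is smoothed (300
   iterations of the cyclic ¼–½–¼ moving average), decomposed into 20
   harmonics, normalized to the first harmonic, and harmonics 2–20 (76
   coefficients per face) become the shape features. Faces are
   concatenated, giving 228 variables for the three-face analysis.
5. **Statistics.** Per-face PCA on the correlation matrix with
   Kaiser-criterion retention (eigenvalue > 1); canonical discriminant
   analysis (CDA) on the concatenated retained scores with Wilks' Λ and
   Rao's F; classification by Mahalanobis distance to group centroids in
   canonical space with equal priors (proportional available);
   resubstitution and leave-one-out jackknife confusion tables; per-species
   ordinary least squares of the specimen-mean NEF coefficient on statolith
   length (allometry).

## Elliptical Fourier conventions

**Decomposition.** For a closed polygon with segment vectors
(Δx_i, Δy_i), chord lengths Δt_i, cumulative arc length t_i and perimeter
T, the coefficients of harmonic n are the exact Fourier integrals of the
piecewise-linear curve (chain-sum form):

    A_n = T/(2 n² π²) Σ_i (Δx_i/Δt_i) [cos φ_i − cos φ_{i−1}],   φ_i = 2π n t_i / T

and analogously for B (sin, Δx), C (cos, Δy), D (sin, Δy). Because these
are exact on the polygon, the coefficients do not depend on how densely the
polygon is sampled — no FFT and no resampling step is involved. The DC
terms are the arc-length averages of x and y.

**The parameterization is arc length, and that matters.** A coefficient
set describes x(t), y(t) of a uniform parameter; the curve it traces,
re-decomposed, is parameterized by its own arc length, which is a different
parameter whenever the first-harmonic ellipse is eccentric. Three practical
consequences, all measured in this codebase:

- A geometric 2:1 ellipse decomposes to A₁ = 1.8279, D₁ = 1.0730 (not 2
  and 1) with a genuine third harmonic A₃ = 0.1284; 0.58 % of its power
  sits above harmonic 1. Only the zero-eccentricity ellipse (a circle) is
  exactly one harmonic. The popular statement "an ellipse is its first
  harmonic" is a property of the elliptic-angle parameterization, not of
  arc-length EFA.
- Synthetic templates defined in coefficient space are therefore refined by
  iterating reconstruct → decompose → normalize toward the arc-length
  consistent fixed point (`arc_length_canonical`, 20 iterations,
  truncation-limited residual ≈ 1e-4 per coefficient), so that template
  coefficients and coefficients measured from template outlines agree.
- A raw pixel boundary is a staircase whose arc length is inflated in a
  direction-dependent way (diagonal chain steps vs axis steps). This
  perturbs harmonic 2 by ~1e-2 *independent of image resolution*. The
  protocol's 300 smoothing iterations remove the staircase and with them
  the bias: the render → extract → smooth → decompose round trip errs by
  0.012 / 0.0035 / 0.0012 per coefficient at 256 / 512 / 1024 px. This is
  the quantitative reason outline smoothing precedes decomposition in
  pixel-based Fourier workflows.

**Normalization.** Size, rotation and trace starting point are removed
using the first harmonic: the starting point is rotated onto the
first-harmonic ellipse's major axis (the stationary-phase angle
θ = ½·atan2(2(A₁B₁+C₁D₁), A₁²+C₁²−B₁²−D₁²), picking the candidate
θ + kπ/2 that lands on the major axis), the shape is rotated so that axis
is horizontal, and all coefficients are divided by the semi-major axis
length. Afterwards A₁ = 1, B₁ = C₁ = 0 and D₁ is the aspect of the best
fitting ellipse. Reflection is *not* removed: a mirrored statolith is a
different shape. The remaining half-period starting-point ambiguity (which
negates every even harmonic) is resolved by a sign convention: the
largest-magnitude coefficient among the even harmonics is made positive.
Under this convention 100 random similarity transforms plus start-shifts
reproduce the coefficients to better than 1e-9 in the test suite.

**Feature vector.** Harmonic 1 is dropped entirely — A₁, B₁, C₁ are
constants after normalization and D₁ depends on how the silhouette was
oriented — leaving the (A, B, C, D) quadruples of harmonics 2–20:
76 variables per face, concatenated in the order proximal, oral, lateral.

**Harmonic power.** power_n = (A_n²+B_n²+C_n²+D_n²)/2; the smallest n
whose cumulative fraction reaches 99 % is logged per silhouette, giving the
"how many harmonics are enough" summary for any data set.

## Statistical conventions

- **PCA.** Correlation-matrix eigendecomposition of the standardized
  features, per face; components with eigenvalue > 1 are retained (Kaiser
  criterion). Zero-variance columns are dropped with a warning. Eigenvector
  signs are fixed by making the largest-magnitude loading positive.
- **CDA.** Generalized eigenproblem B v = λ W v with B the between-group
  and W the pooled within-group SSCP; canonical coefficients are scaled so
  canonical scores have unit pooled within-group variance, hence Euclidean
  distance in canonical space equals pooled-covariance Mahalanobis
  distance. Wilks' Λ = Π 1/(1+λ_i); significance by Rao's F with
  df1 = p(k−1), df2 = wt − p(k−1)/2 + 1, w = N−1−(p+k)/2,
  t = √((p²(k−1)²−4)/(p²+(k−1)²−5)) (t = 1 when degenerate); reported dfs
  are floored to integers, giving (33, 504), (913, 1033) and (415, 489)
  for the study design's three model shapes (p = 3 or 83, k = 12 or 6,
  N = 185). Λ and F are cross-checked against the MANOVA implementation in
  statsmodels in the test suite. A singular W receives a ridge of
  1e-8 × mean diagonal with a warning (needed only for degenerate
  fixtures, e.g. one observation per group).
- **Classification.** argmin over groups of ½·d² − ln(prior) with d the
  canonical-space distance to the centroid; equal priors by default.
  Because the rule is Mahalanobis, confusion tables are invariant to any
  invertible affine map of feature space (asserted in tests), and with
  proportional priors the predictions coincide with linear discriminant
  analysis (cross-checked against scikit-learn).
- **Jackknife.** Each observation is classified by a CDA refitted on the
  other N−1. The PCA reduction is computed once on the full data set and
  held fixed across folds — it is treated as a prior variable-selection
  step of the procedure, not as part of the classifier. A group of size 1
  can never classify its own member correctly; a warning says so.
- **Tukey–Kramer.** q = |mean_i − mean_j| / √(MSW/2·(1/n_i+1/n_j)),
  adjusted p from the studentized-range distribution with (k, N−k);
  cross-checked against statsmodels.
- **Allometry.** Per species (n ≥ 3 required), OLS of the specimen-mean
  feature coefficient on statolith length; the slope t-test p-value is the
  reported quantity. Statolith length is taken from the first configured
  face in canonical order (proximal when present).

## The synthetic data generator

No real statolith silhouette collection is publicly deposited, so the
package ships a generator whose defaults encode the study design the
analysis expects, and all end-to-end claims are tested against it.

- **Structure.** 12 species nested in 6 families with the unequal group
  sizes (12, 20, 20, 11, 9, 17, 20, 12, 20, 20, 4, 20), 185 specimens and
  three faces each. Templates are normalized-style coefficient sets per
  face built from: a per-face baseline (harmonic amplitudes ∝ 1/n², SD
  0.4/n² per coefficient), a family offset (SD 0.21/n²) and a species
  offset (SD 0.07/n², i.e. a 3:1 family:species ratio), drawn once from a
  fixed internal seed so the template library is a reproducible constant.
  First-harmonic aspects differ by face, with proximal faces the most
  elongate view.
- **Within-species noise is low-rank.** Specimens vary along 24 shared
  deformation modes per face (the same 1/n² envelope) carrying ~94 % of
  the noise variance, plus a small iid residual (25 % of the mode scale);
  the marginal per-coefficient SD is 0.12/n². Taxon offsets are drawn
  inside the same mode space. This mode structure is what makes the
  Kaiser-criterion PCA a *useful* step: the retained components are the
  deformation modes, which carry the taxonomic signal, while unstructured
  digitization noise falls below the eigenvalue-1 cut. (With fully
  independent per-coefficient noise the retained components are dominated
  by sampling-noise directions — the upper Marchenko–Pastur edge for
  p = 76, N = 185 is ≈ 2.7 — and species information is discarded;
  measured, this caps species resubstitution near 93 % no matter how far
  apart the species are. Real hard-part variation is mode-structured, and
  the generator follows the realistic model.)
- **Sizes and allometry.** Statolith length is Gaussian per species
  (means 200–450 µm, SD 8 % of the mean). Exactly one species — the
  *Malo maxima* analogue — has allometric drift: across a 3-size-SD span
  of lengths every coefficient moves by 3 of its own noise SDs. All other
  species have zero drift.
- **Rendering.** Outlines are reconstructed at 512 points, scaled so the
  Feret diameter equals the drawn length, checked for simplicity with
  shapely (up to 10 redraws of the noise), and rasterized black-on-white
  with the shape spanning ~78 % of a 512-px canvas; the per-specimen
  µm/px goes into the manifest.
- **Calibrated behaviour.** With these defaults the full image pipeline
  classifies species at 98.9–100 % resubstitution and 87.6–93 % jackknife
  (measured over four generation seeds), families at 100 %, with 13–23
  jackknife misclassifications of which 93–100 % fall within the true
  family — the qualitative ordering of a real statolith study:
  resubstitution flatters, the jackknife is honest, and confusion is a
  within-family affair. The amplitude constants were chosen once to
  produce this ordering with margin and are not otherwise meaningful.
- **What the generator does not emulate.** Cross-face correlation within a
  specimen (faces are drawn independently given the template, matching an
  analysis that concatenates faces without modelling their dependence);
  uneven illumination, blur, or segmentation artefacts beyond rasterization
  itself; biophysical crystal-growth constraints (bipyramidal habit);
  measurement operator variability. Passing the end-to-end tests therefore
  shows the pipeline recovers the statistical structure it assumes from
  clean silhouettes; it does not validate robustness to poor imaging.

## Numerical choices and degenerate inputs

- Tolerances: NEF similarity invariance 1e-6 (achieved ~1e-9); chain-sum
  vs dense-integration oracle 1e-6 (achieved ~1e-9); noise-free template
  identity 5e-4 (truncation floor of the fixed-point refinement); rendered
  round trip ≤ 2e-2 per coefficient at 512 px along the smoothed path.
- Outline validity requires ≥ 3 points and no consecutive duplicates;
  boundary traces with fewer than 3 distinct pixels, all-collinear
  outlines, and zero-perimeter polygons raise `DegenerateShapeError`.
- Thresholding at exactly the threshold value is background for dark
  foreground (`<`) and light foreground (`>`), which makes image inversion
  plus polarity flip an exact symmetry at the 0.5 default.
- `min_harmonics_for_power` returns the computed harmonic count with a
  warning if floating-point shortfall keeps the cumulative fraction below
  the threshold.
- Pipeline outputs are written with a fixed float format (`%.12g`) and
  hashed (SHA-256) into the run log; identical inputs and configuration
  reproduce byte-identical artifacts.

## Problem sizes used by the test suite and acceptance script

The heavy end-to-end checks run the complete default study — 185 specimens,
555 rendered 512-px silhouettes — once per session (about half a minute);
unit and property tests use analytic shapes and a 3-species × 5-specimen
smoke study at 192 px. The acceptance script regenerates the full study at
the caller's seed and recomputes every reported quantity from it.

## Known limitations

- Length is the Feret diameter; if a study defines length along an
  anatomical axis that differs from the caliper axis, values shift by a
  small amount (on real statoliths the two conventions typically agree to within a
  couple of percent), and the package makes no attempt to guess
  anatomical axes.
- The jackknife refits the CDA but not the PCA; fully nested
  cross-validation would be slightly more conservative.
- First-harmonic normalization is undefined for shapes whose first
  harmonic vanishes (e.g. curves traversed twice); these raise
  `NormalizationError` rather than being handled.
- The even-harmonic sign convention can, in principle, flip between two
  nearly-equal leading coefficients under perturbation; for silhouette-like
  shapes with a dominant harmonic 2 this was never observed.
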