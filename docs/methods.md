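# Methods

## The evaluation model

The package evaluates interactive point-to-mask segmentation the way an
expert would drive it: one slice at a time, clicking where the current
contour is wrong, keeping the best contour seen. Formally, for a slice with
ground truth G and a promptable predictor f:

1. p₁ = argmax of the Euclidean distance transform of G (the most interior
   tumor pixel). All prompts are pixel positions with a
   foreground/background label.
2. At iteration k the predictor receives the image and the full ordered
   prompt list and returns three candidate masks M₁..M₃ with confidence
   scores c₁..c₃. One candidate P_k is selected by the strategy under
   evaluation (below) and its IoU against G is recorded.
3. If P_k ≠ G and k < 9, the next prompt is placed at the "center" of the
   set difference: foreground in G∖P_k when |G| ≥ |P_k|, else background in
   P_k∖G. "Center" means the distance-transform argmax of the largest
   8-connected component of the difference — unlike a centroid this always
   lies inside the region, including concave ones.
4. The loop stops after nine prompts or as soon as P_k = G (both set
   differences are then empty, so no further prompt is defined). The
   per-slice primary metric is best IoU = max over recorded iterations; the
   iteration achieving it first is also recorded.

Selection strategies: **oracle** = argmax calculated IoU (models an expert
keeping the best of the three suggestions), **suggested** = argmax reported
confidence (the model's own pick), **prev_slice** = argmax IoU against the
previous slice's final mask (sequential slice-wise use; the first
tumor-containing slice of a volume falls back to oracle selection since no
previous segmentation exists). Ties always resolve to the lowest candidate
index. Each strategy runs its own simulation: the strategy's selected mask
feeds the next prompt, so trajectories differ between strategies.

Only prompts are fed back to the predictor between iterations — no mask or
logit feedback.

## Preprocessing conventions

- Intensities are normalized per 3D dataset: v → round(v · 255 / max),
  round-half-up, before any cropping, so full-slice and cropped experiments
  share intensities. Slices are replicated to three identical 8-bit
  channels (the standard promptable-model input contract).
- Axes are fixed as sagittal = 0, coronal = 1, transverse = 2; voxel
  indices are 0-based and boxes half-open. Every slice whose ground-truth
  plane is nonempty is evaluated, in ascending index order, for all three
  orientations alike.
- The tumor ROI is the per-axis foreground extent padded by
  round(margin / spacing) voxels (default margin 20 mm), clipped to the
  grid; cropped-frame masks are mapped back to the full grid through the
  recorded box offset before any 3D operation.
- Ground-truth slice area is foreground pixel count x in-plane pixel area
  (exact on isotropic grids).

## Stacking and fusion

Per orientation, each traced slice contributes its best-iteration selected
mask; planes without tumor ground truth stay background (they are never
evaluated, so the stacked volume is zero there by construction, and an
orientation simply votes background where it has no prediction). The fused
volume is the per-voxel 2-of-3 majority of the three orientation stacks.
Volumetric Dice scores both; Dice and IoU are related by D = 2J/(1+J),
which the test suite asserts numerically across modules.

## Area statistics

Best IoU is correlated with ground-truth slice area (Spearman, midranks).
The optimal area cutpoint uses maximally selected rank statistics: for each
candidate cutpoint mu (distinct covariate values within the 10-90% quantile
band leaving at least 2 observations per side), the standardized Wilcoxon
rank-sum statistic z(mu) compares responses with x <= mu against x > mu,
using the hypergeometric moments E(S) = n1*a-bar and
Var(S) = n1(N-n1)/(N(N-1)) * sum (a_i - a-bar)^2 over midrank scores a. The
reported cutpoint maximizes |z| (ties -> smallest cutpoint). Because the
maximum is selected over many candidates, the p-value is adjusted by a
seeded permutation scheme (default 1000 permutations) that re-pairs x and y
and recomputes the maximal |z| each time — exact in distribution and
verified to hold its level (rejection rate 0.050 at alpha = 0.05 over 10^4
null replicates). An asymptotic improved-Bonferroni adjustment like the one
in the classical R implementation could be added later; the permutation
route was chosen because it is exact, seedable, and testable.

Known limitation: when the true split is off-center (e.g. a third of the
observations below the true threshold), the argmax of the standardized
statistic drifts one datum past the true inter-datum gap in roughly 7% of
strong-step replicates — the variance term sqrt(n1(N-n1)) grows toward the
median split, so annexing one low-rank observation from the other side can
increase |z|. This is a property of maximally selected Wilcoxon statistics
themselves (an independent re-implementation reproduces it exactly), not of
this implementation; at practical data scales the estimated cutpoint is
still within one observation of the truth.

Group comparisons use the Wilcoxon signed-rank test (paired arms) and
rank-sum test (unpaired), two-sided, via scipy's normal approximation with
tie/continuity handling. Slice-level observations are treated as
independent, matching per-slice analyses common in this setting; clustering
of slices within patients is a recognized caveat, recorded here rather than
corrected.

## Synthetic phantoms

`generate_phantom` builds a labeled volume from `PhantomParams`:

- **Ground truth**: the union of `n_lobes` ellipsoidal lobes. The first
  lobe is a sphere of radius `tumor_radius_mm` (default 10 mm) at a
  uniformly chosen interior point; additional lobes have centers within a
  ball of that radius and semi-axes 0.35-0.6 of it, giving connected,
  irregular cores. The union is smoothed (Gaussian sigma 0.7 voxels,
  re-thresholded at 0.5). Tumors that would touch the grid boundary are
  rejected.
- **Intensity**: a brain-like bright ellipsoid (92% of the grid) with
  smooth texture on a dark surround; a rim shell (mask minus a 2-voxel
  erosion) at brightness proportional to `rim_contrast`; an enhancing
  interior at half that gain; a dimmed necrotic center (innermost
  `necrotic_fraction` of the core by distance transform — still part of the
  ground-truth mask, since the segmentation target is the whole tumor
  core); additive Gaussian noise (`noise_sd`, default 15 on a ~0-800
  arbitrary-unit scale).
- **Grade axis**: `rim_contrast` >= 0.5 tags the volume HGG-like (sharp,
  contrast-enhanced), below LGG-like (diffuse). Study cohorts default to a
  roughly 70/30 high/low-grade mix, mirroring public glioma cohorts.

Defaults for desk-scale experiments use 48x48x40 to 64x64x48 voxel grids at
1 mm isotropic spacing with ~9-10 mm tumor radii — the geometry of the
problem (peripheral small cross-sections through large central ones) at a
size where the full pipeline runs in seconds per volume. What the phantoms
do **not** emulate: MRI physics (bias fields, sequence contrast), multiple
sequences, edema, skull/anatomy, inter-patient anatomical variability.
Passing tests therefore demonstrate the pipeline's correctness and the
qualitative behaviors built into the mock (below), not clinical performance
of any real model.

## Mock promptable predictor

The mock stands in for a real promptable network so every downstream stage
is testable offline. Given a registered slice it returns the ground truth
degraded by seeded morphological noise:

- Degradation magnitude m = max(0, corruption_level − improvement_rate ·
  (n_prompts − 1)) · s, where the contrast scale
  s = clip(0.25 / contrast, 0.5, 3) makes low-contrast (LGG-like) slices
  harder. Contrast is estimated once per study from the normalized volume
  (mean inside the core minus mean in a 3-voxel surrounding ring) so that
  all slices of a study share one difficulty scale; a per-slice estimate
  would make small peripheral slices look artificially sharp (they cut
  mostly through the bright rim), distorting the area-accuracy relation.
- Each candidate draws a severity factor (uniform 0.5-1.6) and a fixed
  random translation/dilation/erosion pattern from a sub-seed stable in
  (predictor seed, image content, candidate index). Because the pattern is
  fixed per candidate and scaled by m, the error field shrinks continuously
  as prompts accumulate — a model refining one prediction — which is what
  makes the mean IoU-vs-prompts curve cleanly monotone at desk-scale slice
  counts (re-rolling the noise every iteration would only be monotone in
  expectation).
- Prompts the candidate contradicts are enforced within a 3-pixel
  neighborhood (foreground prompt outside the candidate pulls a patch in;
  background prompt inside pushes one out); prompts already satisfied do
  nothing, so an exact candidate stays exact and m = 0 reproduces the
  ground truth.
- Confidences blend the candidates' true-IoU ranks with uniform noise:
  conf = calibration · rank/2 + (1 − calibration) · U(0,1). calibration = 1
  makes the suggested strategy coincide with the oracle; calibration = 0
  makes it a uniform pick (1-of-3).
- `ambiguity_mode="whole_object"` replaces one single-prompt candidate with
  the largest bright connected component (the whole brain), reproducing the
  characteristic whole-object failure of promptable models on a single
  ambiguous click. Off by default so that the basic contract
  (corruption 0 → exact candidates) holds under defaults.

All sub-seeds derive from SHA-256 hashes of (root seed, component, image
content, indices): no global RNG state, and identical inputs always give
identical outputs, which is what makes whole-study runs byte-reproducible.

## Problem sizes

Tests and the acceptance run use 20-52 phantoms on 36-48 voxel grids
(hundreds to ~2000 slice traces, matching the runtime of seconds to tens of
seconds per suite that keeps the full pipeline iterable on a laptop). These
sizes were fixed as the package's study conditions; all asserted behaviors
are ordering/monotonicity/calibration properties that are stable at these
scales, not point estimates of any external system.
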