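# Methods

## Coordinates, units and image model

All arrays are row-major with 0-based `(row, col)` indices. Pixel `(r, c)`
covers the unit square `[c, c+1) × [r, r+1)`; its center is
`(c + 0.5, r + 0.5)`. A single isotropic scale `pixel_scale_mm` converts to
physical units; the default `3/304 mm ≈ 9.87 µm` matches a 3 × 3 mm en face
scan sampled on a 304 × 304 grid, and is overridable per image because
device export resolutions vary. Intensities are min–max normalized to
`[0, 1]` on load (a constant image maps to zeros), so every downstream
threshold lives on a fixed scale. Lesion contours are filled by the even–odd
rule with the pixel-center-inside test.

## Binarization chain

`denoise → Frangi vesselness → local adaptive threshold → hole filling →
small-object removal`, intersected with the lesion mask.

The Frangi filter is implemented from Gaussian-derivative Hessians
(γ-normalization exponent 1, i.e. a `σ²` multiplier per scale) with
eigenvalues ordered by magnitude and bright-ridge polarity (λ₂ < 0), maximum
over scales, output normalized by its global maximum. The structureness
cutoff `c` defaults to half the maximum structureness over the image — the
conventional data-adaptive rule. An earlier percentile-based rule was
rejected: with speckle, a percentile of S is dominated by noise texture,
which flattens the second Frangi term and lets noise ridges score like
vessels.

The local adaptive threshold marks a pixel foreground iff its value exceeds
the mean over a `window_px` square (reflective boundary) plus `offset`, with
a `1e-9` guard against the sliding-sum rounding error of the uniform filter
(exact ties, e.g. constant regions, must stay background).

Two further morphological steps are essential in practice and are exposed in
`BinarizeParams`:

* **hole filling** (`fill_holes_px`, default 64): the Frangi response dips
  at blob-like junction zones (they are not ridges), and unfilled holes
  there make the skeleton loop around every junction, inflating junction
  counts and length;
* **small-object removal** (`min_object_px`, default 80): speckle clusters
  that survive thresholding inside the lesion.

Two profiles are provided. The **default** (`sigma_px=1.5`, scales 1–4 px,
β=0.5, window 31, offset 0.10) is calibrated for speckled OCTA-like images
and was selected by a grid search against synthetic ground truth at the
default noise level. `BinarizeParams.clean()` (`sigma_px=0.5`, scales
1–2 px, offset 0.15) suits clean high-contrast images, where fine scales
matched to vessel radii keep the binary map tight (Dice ≥ 0.9 against the
true tube union on clean medusa renders; the default profile trades that
tightness for speckle robustness, which widens vessels and biases vessel
area/density/diameter upward on noisy images). A `threshold_on="intensity"`
flag thresholds the denoised image instead of the vesselness map; which of
the two the original MATLAB chain used is not determinable, so both are
first-class.

## Skeleton graph

Thinning is scikit-image's Zhang–Suen-style 2D `skeletonize` (deterministic,
idempotent). Skeleton pixels are classified by 8-neighbor count
(1 endpoint, 2 interior, ≥3 junction pixel); 8-adjacent junction pixels
merge into one junction cluster, so a 4-valent crossing counts once
(`merge_junctions=False` restores the raw-pixel convention for sensitivity
analyses). Branches are traced edge-by-edge so every skeleton adjacency
belongs to exactly one branch or intra-cluster edge — total length therefore
decomposes exactly over the graph.

Spur pruning (default 3 px) removes endpoint twigs created by thinning wide
vessels. The walk from an endpoint stops at the first pixel with two or more
further continuations; that attachment pixel is itself removed when its
remaining neighbors are mutually 8-connected (a protrusion from a straight
run) and kept when it joins genuinely separate branches.

**Length.** Total vessel length is the classic step sum: 1 px per orthogonal
and √2 px per diagonal adjacency, each counted once. This estimator is known
to overestimate the length of oblique continuous curves by up to ~8 %
(≈ +5.5 % averaged over orientations) — the staircase bias of digital
curves. The synthetic truth therefore reports **both** the continuous
polyline arclength and the step-sum length of the true raster skeleton;
length-recovery checks compare step sum against step sum, which isolates
binarization/thinning error (−3…−4 % mean on clean renders, from tip erosion
of ~1 tube radius per endpoint and fused tube stems near bifurcations) from
the fixed digitization constant.

**Tortuosity.** Per branch, arc length / chord. The arc is measured on the
pixel path after a window-3 moving-average smoothing of its coordinates
(endpoints preserved; cycles smoothed circularly), because the raw step sum
carries the same +5 % staircase bias into the ratio — a digitized
semicircle scores 1.649 raw but 1.567 smoothed against the analytic π/2.
The raw ratio remains available (`Branch.tortuosity`, `smoothed=False`).
Chord conventions: open branches use the endpoint distance; cycles and
branches that leave and re-enter the same junction cluster (endpoint
separation ≤ 3 px) use the path's maximum pairwise distance (the loop
diameter), since an endpoint chord is meaningless for a loop. Degenerate
chords are excluded; an aggregate without valid branches is NaN, never 0.

**Fractal dimension.** Box counting on the skeleton: dyadic box sizes
2, 4, 8, … up to a quarter of the smaller grid dimension (≥3 sizes
required), boxes anchored at the skeleton's bounding-box origin, slope of a
least-squares fit of log N(s) on log(1/s). No grid-offset averaging by
default, for determinism; the implementation reproduces 1.0 / 2.0 /
log 3 / log 2 on a line / filled square / Sierpiński raster within 0.05–0.06.
Single-lesion FD carries sampling noise of roughly ±0.05, which matters for
interpreting small treatment effects (below).

## Cohort statistics

Relative ratio RR = 100 × post-mean / baseline-mean (ratio of group means,
not mean of per-eye ratios), decrease% = 100 − RR, both to 2 decimals.
Paired comparisons offer both the rank-sum (Mann–Whitney on the two
timepoints) and the Wilcoxon signed-rank test on differences; reports
default to rank_sum and record the method, since the two are not
interchangeable and published cohort tables in this area name the rank-sum
test for paired data. Exact permutation nulls are used for n ≤ 12, the
continuity-corrected normal approximation beyond (the two agree within 0.02
already at n = 12; type-I error at α = 0.05 over 1000 null cohorts of 29
eyes is ~0.045). Spearman correlations use tie-averaged ranks with strength
labels: |r| ≥ 0.90 very strong, 0.70–0.89 strong, 0.40–0.69 moderate,
0.10–0.39 weak, else negligible. No multiple-testing correction is applied,
matching the reference analysis. Missing values (fully regressed lesions
with no post panel, "NA" refractions) are excluded, never imputed; RR rows
whose printed reference values were computed from unrounded means (vessel
density, tortuosity) are flagged and excluded from numeric comparisons.
CRT is treated as micrometres throughout (values ≈ 317 µm; a "mm" unit label
in the reference table is anatomically implausible).

## Synthetic networks and what they do (not) show

The generator grows depth-limited stochastic bifurcation trees:
per-branch random-walk polylines (step 2.5 px, angle jitter 0.12 rad),
branching probability 0.85 to depth 3, exponential caliber decay 0.8 from a
4 px root, phenotype-specific seeding (medusa: radial primaries on a small
hub ring; sea-fan: primaries staggered along a 60° arc of the lesion border;
tree-in-bud: compact, no dominant trunk; disorganized loops: sparse short
segments, literal closed-loop polylines, and anastomoses placed only where
they form an unambiguous T). Growth maintains a minimum 8 px separation
between unrelated centerlines, and a bifurcation is recorded only when both
children actually grew past the junction region — together these make the
recorded topology exactly the topology a skeleton of the rendered image can
recover, which is what "junction count exact" tests mean. The lesion outline
is the inflated convex hull of the network.

Rendering draws each segment as a tube of its caliber at intensity 1, adds
background 0.12, multiplies by lognormal speckle (σ = 0.3), and blurs
(σ = 0.8 px). The treatment transform deletes segments below a pruning
caliber (with orphaned descendants), dilates survivors (≥1), and shrinks the
lesion to the survivors' hull. The simulated cohort (30 eyes, per-eye prune
caliber U(2.1, 2.7) px crossing the two deepest generations, dilation
U(1.02, 1.15)) reproduces the clinical ordering — junction count drops most
(RR ≈ 45–55 %), fractal dimension least, diameter increases — and CRT is
co-simulated to track lesion-area percent change with noise, yielding the
moderate correlation regime.

What passing these tests does **not** show: the generator has no
hemodynamics, no projection artifacts, no segmentation error, and its noise
is a first-order speckle model; phenotype parameters are chosen to land in
the reported biomarker ranges, not fitted to data. Agreement on synthetic
networks validates the measurement chain, not the clinical claims.

Two directions are population-level by nature: under leaf-level pruning the
fractal dimension (estimation noise ±0.05 vs a per-lesion effect of
−0.01…−0.05) and the junction density (individual trees can lose length
faster than junctions) decrease in ensemble mean but not in every single
network — consistent with the reference values themselves being cohort
means.

## Problem sizes

Validation runs use 20 seeded networks per phenotype on 304 × 304 grids,
30-eye simulated cohorts, and 1000-replicate null simulations for test
calibration; the per-eye skeletons carry ~10–30 junctions versus ~50 in the
clinical cohort, so simulated cohort statistics are scale-reduced but
direction- and ordering-faithful.

## Known limitations

* Vessel area (and therefore density and diameter) from the speckle-robust
  default profile is biased upward on noisy images (tube dilation); the
  clean profile removes the bias on high-quality inputs.
* The disorganized-loops phenotype has 0–2 true junctions per lesion;
  junction recovery there is "within ±1", not a meaningful percentage.
* 4-valent crossings count as one junction under the default clustering;
  analyzers that report two triple-points will disagree on crossing-rich
  lesions (the raw-pixel flag quantifies the gap).
* The pipeline quantifies a supplied lesion outline; it neither detects
  lesions nor corrects segmentation or projection artifacts.
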