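# Methods

This note records the models implemented in `ccparc`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
phantoms do and do not establish.

## Coordinate and intensity conventions

All modules index arrays `(row, col)` with row 0 at the top. "Anterior" is
toward smaller columns by default; every parcellation entry point accepts
`flip_anterior`. Intensities are min–max normalized to [0, 1] (a constant
image maps to zeros); normalization is idempotent, so re-entrant calls are
safe. The pipeline normalizes *before* diffusing, so the diffusion edge
threshold κ is quoted on the [0, 1] scale there (default 0.10), while the
standalone `ADFParams` default (κ = 30) suits raw 8-bit-scale input.

## Anisotropic diffusion

Perona–Malik with a 4-connected stencil, explicit time stepping
(λ ≤ 0.25 for stability), reflecting boundaries, and exponential
(default) or rational conductance. Reflecting boundaries make the scheme
conservative (global mean preserved to rounding), and because the update
is a convex combination for λ Σ g ≤ 1 the output never leaves the input
intensity range (maximum principle). Defaults: 15 iterations standalone,
10 in the pipeline — enough to suppress mild acquisition noise without
rounding the arch's corners.

## Pixel classification and model selection

The feature space is normalized intensity only; this keeps the classifier
well-posed, matches the visual character of cluster maps on midsagittal
slices, and makes every stage cheaply reproducible. K-means (Lloyd, up to
300 iterations, deterministic seed) provides k candidate classes; each
class keeps up to 512 "pattern units" (member intensities, subsampled
evenly by rank so the choice is deterministic). The PNN assigns a pixel to
the class with the largest average Gaussian kernel density over its
pattern units; the shared kernel width defaults to half the mean
nearest-other-centre gap. Exact density ties break toward the smaller
class index.

The class count is selected by maximizing a validity index built from
three normalized entropy terms:

    Vmep(k) = H_between/log k − mean_c H_within(c)/log B − mean_i H(q_i)/log k

* `H_between`: Shannon entropy of class proportions. Balanced partitions
  score 1 after normalization (the maximum-entropy principle applied to
  the partition itself).
* `H_within(c)`: entropy of class c's intensity histogram over B = 64 bins
  spanning [0, 1]. This punishes *under*-segmentation: merging two
  plateaus produces a bimodal class histogram.
* `H(q_i)`: mean entropy of per-pixel posterior memberships under a Parzen
  model refit from the map, with per-class bandwidth equal to the
  within-class standard deviation (floored at 1e-3). This punishes
  *over*-segmentation: splitting one plateau yields two overlapping
  densities and ambiguous posteriors. A bandwidth tied to within-class
  spread is essential here — a between-centre bandwidth smears posteriors
  even for a correct clustering and was rejected for that reason.

The two penalty terms are complementary; with only one of them the index
can be made arbitrarily good by merging into balanced groups or by
splitting compact ones (closed-form entropy arithmetic on Gaussian
plateaus shows a split class costs only ~log 2 within-entropy while the
balanced between-term stays at its ceiling). Posterior entropy is
evaluated on an every-nth-pixel subsample (≤ 4096 pixels, ≤ 256 units per
class), keeping the score deterministic. Empty classes and k < 2 are
validation errors. Ties across k prefer the smaller k.

On plateau phantoms with level separation ≥ 5 noise sigmas the index
recovers the generating class count in 20/20 seeds for both two- and
three-plateau images (see `tests/test_acceptance.py`). On real arch
phantoms after diffusion the selected k is often 4–5 rather than 3: edge
pixels blurred between tissue classes support an extra class. This is
harmless downstream because CC isolation only needs the brightest class
to be pure.

## CC isolation

The CC class is the cluster class with the highest mean intensity (the CC
is the brightest white-matter structure in midsagittal T1). A radius-1
morphological opening detaches thin bridges such as the fornix; remaining
8-connected components are scored by `area · exp(−d²/2τ²)` with d the
distance from the component centroid to a point at (0.45·H, 0.5·W) —
slightly above centre, where the CC sits — and τ = 25 % of the image
diagonal. Components below 0.1 % of the image area are ignored; if none
survives, a "CC not found" error is raised. The winner is returned as a
single-component mask.

Contours are traced with Moore-neighbour following and Jacob's stopping
criterion, walking the (pixel, backtrack) state graph so termination is
guaranteed. Border pixels are defined as mask pixels with a 4-connected
background neighbour (mask minus cross-erosion), which is exactly the set
Moore tracing visits. For hole-free masks the closed chain covers each
border pixel once; masks with interior holes yield the outer boundary
only, and one-pixel-wide necks are traversed twice — both are documented
limitations rather than errors.

## SLIC

Seeds sit on a regular grid with spacing S = √(N/K) (N = in-scope pixel
count; K defaults to 200, the value appropriate for 256×256 slices),
perturbed to the lowest-gradient position in a 3×3 neighbourhood, with
duplicates dropped. Assignment searches a 2S×2S window per centre; centres
update to the member mean and iteration stops after 10 rounds or when the
largest centre motion is < 0.5 px, followed by one final assignment pass
so labels are consistent with the converged centres. In-scope pixels
missed by every window (possible near ragged ROI edges) attach to the
spatially nearest centre. A post-pass enforces 4-connectivity: each
fragment that is not its superpixel's largest component is absorbed by the
adjacent superpixel with the greatest contact length (ties to the smaller
label), iterated to a fixed point; final centres are then recomputed and
labels compacted to {1..K′}.

Two distance formulations are implemented. The default assignment
distance is `D = √(I_d² + e²·(S_d/S)²)` with `I_d = |N_j − N_i|`: the
compactness coefficient e ∈ [0, 1] (default 0.5) then genuinely trades
intensity adherence against spatial regularity, and flat regions tile
into near-square cells. The alternative combined form
`C_d = √(I_d²·(S_d/S)² + e²)` is exposed both as the unit function
`combined_distance` and as `distance_mode="paper_literal"`; note that
inside an argmin its e² term is an inert constant and the remaining
product is zero whenever I_d = 0, so in this mode a deterministic spatial
tie-break (smaller S_d, then smaller label) is applied. The additive-sum
intensity form `√(N_j + N_i)` is likewise available as
`intensity_mode="paper_literal"`; it is not a metric (it is largest for
two bright pixels regardless of similarity) and is off by default.

Invariants verified by tests: exact partition of the scope, one
4-connected component per superpixel, member-to-centre Chebyshev distance
≤ 2S, bitwise determinism, step-edge boundary recall ≥ 0.95, and mean
isoperimetric compactness non-decreasing in e.

## Parcellation

The anterior–posterior axis is the mask's first principal component
(covariance eigenvector), oriented by the anterior convention; a
near-isotropic mask (eigenvalue ratio > 0.95) falls back to the column
axis with a logged warning. Positions project to t ∈ [0, 1] over
[min, max] projection; with this convention the integer cut column on an
axis-aligned rectangle of extent L equals ⌊f·L⌋ for each scheme fraction
f, and a pixel exactly on a cut joins the posterior parcel.

Geometric schemes: Witelson (1/3, 1/2, 2/3, 4/5) and Hofer (1/6, 1/2,
2/3, 3/4). Both cut at 1/2 and 2/3, so their third parcels coincide
pixelwise — a useful exactness check.

The superpixel grouping is this package's design: 1-D K-means (k = 5) on
superpixel-centroid projections, samples weighted by mean superpixel
intensity, with farthest-point initialization (first seed at the minimum
projection, ties broken toward smaller values) so the result is
deterministic. Groups are relabelled 1..5 by ascending mean projection; a
degenerate outcome (< 5 non-empty groups) falls back to projection
quantiles. Pixels inherit their superpixel's parcel, and a contiguity
repair reassigns fragments disconnected from their parcel's main body to
the adjacent parcel with the longest shared border (ties to the smaller
label), iterated to a fixed point. Alternatives considered: grouping on
an arc-length coordinate would match curved ground truth more closely on
strongly bent arches but behaves poorly on near-convex masks where the
angle about the centroid is not monotone along the structure; the linear
projection is robust and recovers equal-arc bands with Dice ≥ 0.9 on the
default phantom geometry.

## Evaluation

One-vs-rest confusion counts per parcel over the full image by default —
true negatives include background, which is what makes accuracy and
specificity near 1 for small structures; `roi_only=True` restricts the
domain to the union of the two foregrounds. Dice of two empty masks is
defined as 1.0 (agreement on absence, logged); other ratios with zero
denominator report NaN rather than raising. Reports append mean and
standard-deviation (ddof = 1) rows; pairwise tables give per-parcel Dice
for every unordered pair of named maps.

## Phantoms

The phantom emulates the configuration the pipeline must disambiguate: a
bright arch (upper half of an elliptical annulus; default midline radii
0.30·W × 0.13·H, thickness ≈ 0.047·H, centred at (0.46·H, 0.5·W)), two
darker tissue blobs, an optional 2-px-wide fornix surrogate descending
from the arch's posterior underside (same intensity as the arch, disjoint
from but 8-adjacent to it), and additive Gaussian noise clipped to [0, 1].
Default intensities 0.85/0.45/0.10 with σ = 0.03 keep class separations
at ≥ 5σ — the "easy" preset representing a clean acquisition. Ground-truth
parcels are five equal arc-length bands of the midline ellipse, anterior
to posterior (the natural analogue of geometric schemes on a curved
structure); band boundaries come from numerically integrated elliptical
arc length and agree with the equal-split targets to within one pixel of
arc.

What passing on phantoms shows: every stage's contracts hold and the
pipeline as a whole recovers a known bright arch and its bands under
Gaussian noise with a fornix-like trap present. What it does not show:
robustness to bias fields, partial-volume effects, Rician noise,
pathological anatomy, or mis-oriented slices — real-scan performance
requires real data and expert ground truth, which are outside this
package's scope. Accordingly the test suite asserts recovery rates
(e.g. 18/20 seeds end-to-end), not clinical accuracy.

## Problem sizes and determinism

Default problem sizes used by the tests and the acceptance script:
256×256 end-to-end phantoms (20 seeds in the test suite, 5 in the
script), 128×128 phantoms for per-stage checks, 48×48 plateau images for
model selection (20 seeds), and 16×16 grids for the brute-force oracles.
Every stochastic step (K-means init, noise generation) is driven by an
explicit integer seed; there is no hidden global RNG state, so identical
inputs and seeds reproduce every artifact bit-for-bit, which the manifest
checksums in `ccparc.pipeline` make easy to verify.
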