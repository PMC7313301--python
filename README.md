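# ccparc — unsupervised corpus-callosum parcellation for midsagittal MRI

The corpus callosum (CC) is the largest white-matter fibre tract in the
human brain and appears hyperintense in midsagittal T1-weighted MRI. Its
subdivision into five sub-regions (rostrum, genu, body, isthmus, splenium)
— *parcellation* — underpins studies of neurodegenerative and developmental
disease, but the structure has no visible internal landmarks, so classical
schemes cut it at fixed geometric fractions regardless of the individual
anatomy. `ccparc` implements a fully automatic, non-geometric alternative
for neuroimaging researchers, together with the geometric baselines and an
evaluation harness, exercisable end-to-end on synthetic phantoms with exact
ground truth.

## Method

Given a 2-D midsagittal slice, the pipeline runs:

1. **Anisotropic diffusion** (Perona–Malik, 4-neighbour explicit scheme):
   `u ← u + λ Σ_d g(∇_d u) ∇_d u` with `g(x) = exp(−(x/κ)²)`, smoothing
   noise while preserving structure edges.
2. **Unsupervised classification**: K-means defines candidate intensity
   classes; a probabilistic neural network (Parzen-window classifier)
   assigns every pixel to the class of maximal Gaussian-kernel density. The
   class count k is chosen automatically by a maximum-entropy validity
   index `Vmep(k) = H_between/log k − mean_c H_within(c)/log B −
   mean_i H(q_i)/log k`, maximized at the best-supported k.
3. **CC isolation**: the brightest class is opened (radius 1) to detach the
   fornix — a thin neighbouring tract of similar intensity — and the
   component maximizing `area · exp(−d²/2τ²)` (d = distance to the
   central-upper image region) is kept; its closed contour is traced by
   Moore-neighbour following.
4. **SLIC superpixels** inside the CC mask: localized K-means with seed
   spacing `S = √(N/K)` (K = 200 by default), spatial distance
   `S_d = √((p_j−p_i)² + (q_j−q_i)²)`, intensity distance `I_d`, and a
   combined distance weighted by the compactness coefficient `e ∈ [0, 1]`.
5. **Five-parcel grouping**: superpixel centroids are projected on the CC's
   anterior–posterior principal axis and grouped into five ordered parcels
   by deterministic 1-D K-means, with a contiguity repair.

Geometric baselines cut the anterior–posterior extent at the Witelson
fractions (1/3, 1/2, 2/3, 4/5) or the Hofer fractions (1/6, 1/2, 2/3,
3/4). Evaluation reports per-parcel Dice = 2TP/(2TP+FP+FN), accuracy,
sensitivity, specificity and precision, plus pairwise inter-method Dice
tables.

## Worked example

```python
import numpy as np
from ccparc import phantoms, evaluation
from ccparc.pipeline import run_pipeline, PipelineConfig

bundle = phantoms.make_phantom(phantoms.easy_preset(seed=1))
res = run_pipeline(bundle.image, PipelineConfig(seed=1))

cc, gt = res["cc_mask"].mask, bundle.cc_mask.mask
print("selected k:", res["cluster_map"].k)
print("CC Dice:", round(2 * (cc & gt).sum() / (cc.sum() + gt.sum()), 4))
print("parcel Dice:", [
    round(evaluation.dice(evaluation.confusion(res["parcels"]["slic"],
                                               bundle.parcels_gt, p)), 3)
    for p in range(1, 6)
])
```

prints

```
selected k: 5
CC Dice: 0.9983
parcel Dice: [0.943, 0.919, 0.96, 0.935, 0.949]
```

i.e. the classifier settles on five intensity classes for this noisy slice,
the isolated CC overlaps the true arch almost perfectly (Dice 0.998 on a
256×256 phantom), and each of the five recovered parcels overlaps its
ground-truth band with Dice ≥ 0.92.

The same pipeline is available from the shell:

```sh
ccparc phantom --out ph --seed 1
ccparc run ph/image.tiff --out results_dir --truth ph/parcels_gt.png --seed 1
ccparc evaluate results_dir/parcels_slic.png ph/parcels_gt.png
```

## Layout

- `ccparc.image_io` — PNG/TIFF/NIfTI reading, 16-bit label maps, min–max
  normalization, shared (row, col) conventions
- `ccparc.preprocess` — Perona–Malik anisotropic diffusion
- `ccparc.clustering` — K-means + PNN classification, Vmep model selection
- `ccparc.cc_isolation` — CC component selection, fornix removal, contour
- `ccparc.slic` — grayscale SLIC (whole-slice or ROI mode)
- `ccparc.parcellation` — SLIC-based and Witelson/Hofer parcellations
- `ccparc.evaluation` — confusion counts, five metrics, pairwise tables
- `ccparc.phantoms` — synthetic slices with exact ground truth
- `ccparc.pipeline` / `ccparc.cli` — orchestration, manifests, `ccparc` CLI

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
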