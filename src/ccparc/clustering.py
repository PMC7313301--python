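"""Unsupervised pixel classification with automatic class-count selection.

Three stages, all operating on normalized scalar intensity:

1. :func:`kmeans_centers` — Lloyd K-means defines candidate intensity classes
   and collects per-class pattern units (member intensities).
2. :func:`pnn_classify` — a probabilistic neural network (Parzen-window
   classifier): each pixel goes to the class whose Gaussian-kernel density,
   averaged over that class's pattern units, is maximal. Ties break toward
   the smaller class index.
3. :func:`vmep_score` / :func:`select_num_classes` — a maximum-entropy
   cluster-validity index picks the class count whose clustering is best
   supported by the data.

The validity index combines three normalized entropy terms::

    Vmep = H_between/log k  -  mean_c H_within(c)/log B  -  mean_i H(q_i)/log k

* ``H_between`` — Shannon entropy of the class proportions: balanced,
  well-populated classes score high (maximum-entropy principle on the
  partition).
* ``H_within(c)`` — entropy of class ``c``'s intensity histogram over ``B``
  bins: compact, unimodal classes score low; merging two plateaus into one
  class is penalized here.
* ``H(q_i)`` — entropy of pixel ``i``'s posterior class membership under a
  Parzen density model refit from the map itself: crisp assignments score
  low; splitting one plateau into two overlapping classes is penalized here.

A perfectly balanced, compact, unambiguous clustering scores close to 1
regardless of k, so the index is comparable across class counts and peaks at
the best-supported one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassModel",
    "ClusterMap",
    "kmeans_centers",
    "pnn_classify",
    "vmep_score",
    "select_num_classes",
]

#: Histogram bins for the within-class intensity entropy term.
VMEP_BINS = 64
#: Cap on per-class pattern units kept for the PNN (evenly spaced by rank).
MAX_PATTERN_UNITS = 512


@dataclass
class ClassModel:
    """K-means-derived class model feeding the PNN.

    ``centers`` are sorted ascending; ``pattern_units[c]`` holds class c's
    (subsampled) member intensities; ``sigma`` is the shared Gaussian kernel
    width on the normalized-intensity scale.
    """

    k: int
    centers: np.ndarray
    sigma: float
    pattern_units: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).ravel()
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.centers.size != self.k:
            raise ValueError("number of centers must equal k")
        if np.unique(self.centers).size != self.k:
            raise ValueError("class centers must be pairwise distinct")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class ClusterMap:
    """Per-pixel class assignment, labels in {1..k}; ``vmep`` set by selection."""

    labels: np.ndarray
    k: int
    vmep: float | None = None


def _nearest_gap_sigma(centers: np.ndarray) -> float:
    """Default kernel width: half the mean nearest-other-centre distance."""
    d = np.abs(centers[:, None] - centers[None, :])
    np.fill_diagonal(d, np.inf)
    sigma = 0.5 * float(d.min(axis=1).mean())
    return max(sigma, 1e-6)


def _even_subsample(sorted_vals: np.ndarray, limit: int) -> np.ndarray:
    if sorted_vals.size <= limit:
        return sorted_vals
    idx = np.round(np.linspace(0, sorted_vals.size - 1, limit)).astype(int)
    return sorted_vals[idx]


def kmeans_centers(
    img: np.ndarray,
    k: int,
    seed: int,
    sigma: float | None = None,
    max_pattern_units: int = MAX_PATTERN_UNITS,
) -> ClassModel:
    """Fit k intensity classes by Lloyd K-means (deterministic given seed)."""
    from sklearn.cluster import KMeans

    x = np.asarray(img, dtype=np.float64).ravel()
    if not np.isfinite(x).all():
        raise ValueError("image contains non-finite intensities")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > np.unique(x).size:
        raise ValueError(
            f"k={k} exceeds the number of distinct intensities ({np.unique(x).size})"
        )
    km = KMeans(
        n_clusters=k,
        n_init=1,
        max_iter=300,
        tol=1e-12,
        random_state=int(seed),
    ).fit(x[:, None])
    centers = np.sort(km.cluster_centers_.ravel())
    if np.unique(centers).size != k:
        raise ValueError("K-means produced duplicate centroids")
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    units = []
    for c in range(k):
        vals = np.sort(x[assign == c])
        if vals.size == 0:
            raise ValueError("K-means produced an empty class")
        units.append(_even_subsample(vals, max_pattern_units))
    if sigma is None:
        sigma = _nearest_gap_sigma(centers)
    return ClassModel(k=k, centers=centers, sigma=float(sigma), pattern_units=units)


def _parzen_scores(
    x: np.ndarray,
    units: list[np.ndarray],
    sigma,
    chunk: int = 16384,
) -> np.ndarray:
    """Per-class average Gaussian-kernel density at each value of ``x``.

    ``sigma`` may be a scalar (shared width) or a per-class sequence.
    """
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=np.float64), (len(units),))
    out = np.empty((x.size, len(units)), dtype=np.float64)
    for start in range(0, x.size, chunk):
        xs = x[start : start + chunk, None]
        for c, u in enumerate(units):
            inv = 1.0 / (2.0 * sigmas[c] * sigmas[c])
            out[start : start + chunk, c] = np.exp(
                -((xs - u[None, :]) ** 2) * inv
            ).mean(axis=1) / sigmas[c]
    return out


def pnn_classify(img: np.ndarray, model: ClassModel) -> ClusterMap:
    """Assign each pixel to the class of maximal Parzen density; deterministic."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    units = model.pattern_units
    if len(units) != model.k or any(u.size == 0 for u in units):
        raise ValueError("model must carry non-empty pattern units for every class")
    scores = _parzen_scores(img.ravel(), units, model.sigma)
    labels = scores.argmax(axis=1).astype(np.int32) + 1  # argmax -> lower index on ties
    return ClusterMap(labels=labels.reshape(img.shape), k=model.k)


def _hist_entropy(vals: np.ndarray, bins: int, rng: tuple[float, float]) -> float:
    h, _ = np.histogram(vals, bins=bins, range=rng)
    p = h[h > 0] / h.sum()
    return float(-(p * np.log(p)).sum())


def vmep_score(
    cmap: ClusterMap,
    img: np.ndarray,
    bins: int = VMEP_BINS,
    max_eval: int = 4096,
    max_units: int = 256,
) -> float:
    """Maximum-entropy cluster-validity index; larger = better supported."""
    x = np.asarray(img, dtype=np.float64).ravel()
    labels = np.asarray(cmap.labels).ravel()
    if labels.size != x.size:
        raise ValueError("cluster map and image shapes differ")
    k = int(cmap.k)
    if k < 2:
        raise ValueError("validity index requires at least 2 classes")
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if counts.size != k or (counts == 0).any():
        raise ValueError("cluster map has an empty class")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("cluster labels must lie in {1..k}")

    p = counts / counts.sum()
    h_between = float(-(p * np.log(p)).sum())

    lo, hi = float(x.min()), float(x.max())
    rng = (0.0, 1.0) if (lo >= -1e-9 and hi <= 1 + 1e-9) else (lo, hi)
    h_within = np.mean([_hist_entropy(x[labels == c], bins, rng) for c in range(1, k + 1)])

    # Posterior crispness under a Parzen model refit from the map itself.
    # Per-class bandwidth = within-class spread, so overlapping (split)
    # classes yield genuinely ambiguous posteriors while well-separated
    # classes stay crisp.
    sigmas = np.array(
        [max(float(x[labels == c].std()), 1e-3) for c in range(1, k + 1)]
    )
    units = [
        _even_subsample(np.sort(x[labels == c]), max_units) for c in range(1, k + 1)
    ]
    stride = max(1, int(np.ceil(x.size / max_eval)))
    xs = x[::stride]
    dens = _parzen_scores(xs, units, sigmas)
    post = dens * p[None, :]
    tot = post.sum(axis=1, keepdims=True)
    ok = tot[:, 0] > 1e-300
    q = np.full_like(post, 1.0 / k)
    q[ok] = post[ok] / tot[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        lq = np.where(q > 0, np.log(q), 0.0)
    h_post = float(-(q * lq).sum(axis=1).mean())

    return (
        h_between / np.log(k)
        - float(h_within) / np.log(bins)
        - h_post / np.log(k)
    )


def select_num_classes(
    img: np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    sigma: float | None = None,
) -> ClusterMap:
    """Pick the class count maximizing the validity index; ties -> smaller k."""
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min > k_max:
        raise ValueError(f"empty class-count range: [{k_min}, {k_max}]")
    if k_min < 2 or k_max > 10:
        raise ValueError(f"class-count range must lie within [2, 10], got {k_range}")
    best: ClusterMap | None = None
    for k in range(k_min, k_max + 1):
        try:
            model = kmeans_centers(img, k, seed=seed, sigma=sigma)
        except ValueError:
            continue  # k exceeds distinct intensities etc.
        cmap = pnn_classify(img, model)
        try:
            cmap.vmep = vmep_score(cmap, img)
        except ValueError:
            continue  # degenerate clustering (empty class after PNN)
        if best is None or cmap.vmep > best.vmep:  # strict: ties keep smaller k
            best = cmap
    if best is None:
        raise ValueError("no valid clustering found in the given class-count range")
    return best
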