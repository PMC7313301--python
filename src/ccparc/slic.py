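"""SLIC superpixel generation on grayscale slices, whole-image or ROI-restricted.

Simple Linear Iterative Clustering is a localized K-means over joint
spatial/intensity coordinates. With N in-scope pixels and K requested
superpixels the initial seed grid has spacing

    S = sqrt(N / K),

each pixel is compared only to centres within a 2S x 2S search window, and
centres are iteratively re-estimated as the mean (row, col, intensity) of
their members. The elementary distances are

    S_d = sqrt((p_j - p_i)^2 + (q_j - q_i)^2)          (spatial)
    I_d = |N_j - N_i|                                  (intensity, default)
    I_d = sqrt(N_j + N_i)                              (intensity, "paper_literal")
    C_d = sqrt(I_d^2 * (S_d / S)^2 + e^2)              (combined, "paper_literal")
    D   = sqrt(I_d^2 + e^2 * (S_d / S)^2)              (combined, default)

where ``e`` in [0, 1] is the compactness coefficient: larger values weight
spatial proximity more, giving more regular superpixels. The combined form
printed as C_d above is kept available but is not the default: its ``e`` term
is an additive constant that cannot influence an argmin, and the remaining
product collapses to an all-way tie wherever I_d = 0, so it degenerates on
flat regions (a deterministic spatial tie-break is applied when it is
selected). A post-pass enforces 4-connectivity by relabelling orphan
fragments into the dominant adjacent superpixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "SlicParams",
    "SuperpixelMap",
    "grid_size",
    "spatial_distance",
    "intensity_distance",
    "combined_distance",
    "slic_segment",
]

_INTENSITY_MODES = ("absolute", "paper_literal")
_DISTANCE_MODES = ("standard", "paper_literal")


@dataclass(frozen=True)
class SlicParams:
    """Superpixel settings; K=200 suits 256x256 slices."""

    n_superpixels: int = 200
    compactness: float = 0.5
    max_iters: int = 10
    intensity_mode: str = "absolute"
    distance_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ValueError(f"need at least 2 superpixels, got {self.n_superpixels}")
        if not 0.0 <= self.compactness <= 1.0:
            raise ValueError(f"compactness must lie in [0, 1], got {self.compactness}")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.intensity_mode not in _INTENSITY_MODES:
            raise ValueError(f"intensity_mode must be one of {_INTENSITY_MODES}")
        if self.distance_mode not in _DISTANCE_MODES:
            raise ValueError(f"distance_mode must be one of {_DISTANCE_MODES}")


@dataclass
class SuperpixelMap:
    """Labels in {1..K'} over the in-scope pixels (0 outside), with centres.

    ``centers[i]`` = (row, col, mean normalized intensity) of superpixel i+1;
    ``grid_size`` is the seed spacing S actually used.
    """

    labels: np.ndarray
    centers: np.ndarray
    grid_size: float


def grid_size(n_pixels: int, n_superpixels: int) -> float:
    """Initial seed spacing S = sqrt(N / K)."""
    if n_superpixels < 1:
        raise ValueError(f"superpixel count must be >= 1, got {n_superpixels}")
    if n_pixels < n_superpixels:
        raise ValueError(f"need N >= K, got N={n_pixels}, K={n_superpixels}")
    return float(np.sqrt(n_pixels / n_superpixels))


def spatial_distance(pi, pj) -> float:
    """Euclidean distance between two (row, col) points."""
    (ri, ci), (rj, cj) = pi, pj
    return float(np.hypot(rj - ri, cj - ci))


def intensity_distance(ni: float, nj: float, mode: str = "absolute") -> float:
    """Distance between two normalized intensities.

    ``absolute`` is |N_j - N_i|; ``paper_literal`` is sqrt(N_j + N_i).
    """
    if mode not in _INTENSITY_MODES:
        raise ValueError(f"mode must be one of {_INTENSITY_MODES}, got {mode!r}")
    if not (0.0 <= ni <= 1.0 and 0.0 <= nj <= 1.0):
        raise ValueError(f"normalized intensities must lie in [0, 1], got {ni}, {nj}")
    if mode == "paper_literal":
        return float(np.sqrt(nj + ni))
    return float(abs(nj - ni))


def combined_distance(i_d: float, s_d: float, s: float, e: float) -> float:
    """Combined spatial/intensity distance C_d = sqrt(I_d^2 (S_d/S)^2 + e^2)."""
    if s <= 0:
        raise ValueError(f"grid size S must be positive, got {s}")
    return float(np.sqrt((i_d * s_d / s) ** 2 + e * e))


def _seed_grid(scope: np.ndarray, s: float, grad: np.ndarray) -> np.ndarray:
    """Regular S-spaced seeds inside scope, perturbed to the local gradient minimum."""
    h, w = scope.shape
    rows = np.arange(s / 2.0, h, s)
    cols = np.arange(s / 2.0, w, s)
    seeds = []
    taken = set()
    for r in rows:
        for c in cols:
            ri, ci = int(round(r)), int(round(c))
            ri, ci = min(ri, h - 1), min(ci, w - 1)
            if not scope[ri, ci]:
                continue
            # 3x3 gradient perturbation; ties resolve row-major.
            best = (np.inf, ri, ci)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = ri + dr, ci + dc
                    if 0 <= rr < h and 0 <= cc < w and scope[rr, cc]:
                        g = grad[rr, cc]
                        if g < best[0]:
                            best = (g, rr, cc)
            if (best[1], best[2]) not in taken:
                taken.add((best[1], best[2]))
                seeds.append((best[1], best[2]))
    return np.array(seeds, dtype=float)


def _enforce_connectivity(labels: np.ndarray, scope: np.ndarray) -> np.ndarray:
    """Relabel 4-disconnected fragments into the dominant adjacent superpixel."""
    comp = measure.label(labels, connectivity=1, background=0)
    n_comp = comp.max()
    if n_comp == 0:
        return labels
    comp_label = np.zeros(n_comp + 1, dtype=np.int64)
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)
    flat_lab = labels.ravel()
    flat_comp = comp.ravel()
    nz = flat_comp > 0
    for cid, lab in zip(flat_comp[nz], flat_lab[nz]):
        if comp_label[cid] == 0:
            comp_label[cid] = lab
    # Main component per label: the largest (ties -> smaller component id).
    main = {}
    for cid in range(1, n_comp + 1):
        lab = comp_label[cid]
        if lab not in main or sizes[cid] > sizes[main[lab]]:
            main[lab] = cid
    resolved = {cid: comp_label[cid] for cid in main.values()}

    # 4-adjacency contact counts between components.
    edges: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = comp
        b = np.roll(comp, -1, axis=axis)
        valid = np.ones_like(comp, dtype=bool)
        if axis == 0:
            valid[-1, :] = False
        else:
            valid[:, -1] = False
        va, vb = a[valid], b[valid]
        diff = (va != vb) & (va > 0) & (vb > 0)
        for x, y in zip(va[diff], vb[diff]):
            key = (int(min(x, y)), int(max(x, y)))
            edges[key] = edges.get(key, 0) + 1
    nbrs: dict[int, dict[int, int]] = {}
    for (x, y), cnt in edges.items():
        nbrs.setdefault(x, {})[y] = cnt
        nbrs.setdefault(y, {})[x] = cnt

    orphans = [cid for cid in range(1, n_comp + 1) if cid not in resolved]
    while orphans:
        progress = False
        remaining = []
        for cid in orphans:
            votes: dict[int, int] = {}
            for other, cnt in nbrs.get(cid, {}).items():
                if other in resolved:
                    lab = resolved[other]
                    votes[lab] = votes.get(lab, 0) + cnt
            if votes:
                # Dominant adjacent label; ties -> smaller label.
                best = max(sorted(votes), key=lambda lab: votes[lab])
                resolved[cid] = best
                progress = True
            else:
                remaining.append(cid)
        if not progress:
            # Isolated orphan cluster (scope not connected): keep own labels.
            for cid in remaining:
                resolved[cid] = comp_label[cid]
            break
        orphans = remaining

    lut = np.zeros(n_comp + 1, dtype=np.int64)
    for cid, lab in resolved.items():
        lut[cid] = lab
    out = lut[comp]
    out[~scope] = 0
    return out


def slic_segment(img: np.ndarray, params: SlicParams | None = None, roi=None) -> SuperpixelMap:
    """Partition the slice (or the ROI mask) into SLIC superpixels.

    Deterministic: seeding, assignment order, and all tie-breaks are fixed,
    so identical inputs give identical label maps.
    """
    if params is None:
        params = SlicParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("slic_segment expects a [0, 1]-normalized image")
    h, w = img.shape
    scope = np.ones((h, w), dtype=bool) if roi is None else np.asarray(
        roi.mask if hasattr(roi, "mask") else roi, dtype=bool
    )
    if scope.shape != img.shape:
        raise ValueError("ROI mask and image shapes differ")
    n = int(scope.sum())
    k = params.n_superpixels
    if k > n:
        raise ValueError(
            f"K={k} exceeds the {n} in-scope pixels; use a smaller K"
        )
    s = grid_size(n, k)

    gr, gc = np.gradient(img)
    grad = np.hypot(gr, gc)
    centers_rc = _seed_grid(scope, s, grad)
    if centers_rc.shape[0] < 1:
        raise ValueError("no seeds fall inside the ROI; use a smaller K")
    centers = np.column_stack(
        [centers_rc, img[centers_rc[:, 0].astype(int), centers_rc[:, 1].astype(int)]]
    )

    rows_idx, cols_idx = np.nonzero(scope)
    literal = params.distance_mode == "paper_literal"
    e = params.compactness

    def assign(ctrs: np.ndarray) -> np.ndarray:
        best = np.full((h, w), np.inf)
        best_sd = np.full((h, w), np.inf)  # spatial tie-break (literal mode)
        lab = np.zeros((h, w), dtype=np.int64)
        win = int(np.ceil(s))
        for i, (cr, cc, ci) in enumerate(ctrs):
            r0, r1 = max(0, int(cr) - win), min(h, int(cr) + win + 1)
            c0, c1 = max(0, int(cc) - win), min(w, int(cc) + win + 1)
            sub = img[r0:r1, c0:c1]
            sc = scope[r0:r1, c0:c1]
            rr, ccol = np.mgrid[r0:r1, c0:c1]
            sd = np.hypot(rr - cr, ccol - cc)
            if params.intensity_mode == "paper_literal":
                idist = np.sqrt(np.clip(sub + ci, 0.0, None))
            else:
                idist = np.abs(sub - ci)
            if literal:
                d = np.sqrt((idist * sd / s) ** 2 + e * e)
                better = sc & (
                    (d < best[r0:r1, c0:c1] - 1e-12)
                    | (
                        (np.abs(d - best[r0:r1, c0:c1]) <= 1e-12)
                        & (sd < best_sd[r0:r1, c0:c1] - 1e-12)
                    )
                )
            else:
                d = np.sqrt(idist**2 + (e * sd / s) ** 2)
                better = sc & (d < best[r0:r1, c0:c1])
            bb = best[r0:r1, c0:c1]
            bb[better] = d[better]
            best[r0:r1, c0:c1] = bb
            bs = best_sd[r0:r1, c0:c1]
            bs[better] = sd[better]
            best_sd[r0:r1, c0:c1] = bs
            ll = lab[r0:r1, c0:c1]
            ll[better] = i + 1
            lab[r0:r1, c0:c1] = ll
        # Pixels outside every window: nearest centre spatially.
        un_r = rows_idx[lab[rows_idx, cols_idx] == 0]
        un_c = cols_idx[lab[rows_idx, cols_idx] == 0]
        if un_r.size:
            d2 = (un_r[:, None] - ctrs[None, :, 0]) ** 2 + (
                un_c[:, None] - ctrs[None, :, 1]
            ) ** 2
            lab[un_r, un_c] = d2.argmin(axis=1) + 1
        return lab

    for _ in range(params.max_iters):
        lab = assign(centers)
        new_centers = centers.copy()
        for i in range(centers.shape[0]):
            m = lab == i + 1
            if m.any():
                rr, cc = np.nonzero(m)
                new_centers[i] = (rr.mean(), cc.mean(), img[m].mean())
        move = np.hypot(
            new_centers[:, 0] - centers[:, 0], new_centers[:, 1] - centers[:, 1]
        ).max()
        centers = new_centers
        if move < 0.5:
            break
    lab = assign(centers)  # final pass consistent with converged centres
    lab = _enforce_connectivity(lab, scope)

    # Compact labels to {1..K'} and recompute final centres.
    present = np.unique(lab[lab > 0])
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int64)
    lut[present] = np.arange(1, present.size + 1)
    lab = lut[lab]
    final_centers = np.empty((present.size, 3))
    for i in range(present.size):
        m = lab == i + 1
        rr, cc = np.nonzero(m)
        final_centers[i] = (rr.mean(), cc.mean(), img[m].mean())
    return SuperpixelMap(labels=lab, centers=final_centers, grid_size=s)
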