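"""Isolate the corpus callosum from a cluster map and trace its contour.

The CC is the brightest white-matter structure in a midsagittal T1 slice, so
the cluster class with the highest mean intensity is taken as the CC class.
Thin bright appendages (the fornix trap) are detached by a radius-1
morphological opening, the remaining 8-connected components are scored by a
spatial prior favouring large components near the image's central-upper
region (where the CC sits in a midsagittal slice), and the best one is kept.

The contour is an ordered, closed, 8-connected chain of border pixels
produced by Moore-neighbour tracing with Jacob's stopping criterion. Border
pixels are those with a 4-connected background neighbour (the mask minus its
cross-erosion). For hole-free masks the chain visits every border pixel;
masks with interior holes yield the outer boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = ["CCMask", "Contour", "CCNotFoundError", "isolate_cc", "trace_contour"]

logger = logging.getLogger(__name__)


class CCNotFoundError(RuntimeError):
    """No plausible CC component found in the cluster map."""


@dataclass
class CCMask:
    """A single 8-connected binary component with summary geometry."""

    mask: np.ndarray
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "CCMask":
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
        n = measure.label(mask, connectivity=2).max()
        if n != 1:
            raise ValueError(f"mask must contain exactly one 8-connected component, got {n}")
        rows, cols = np.nonzero(mask)
        return cls(
            mask=mask,
            area=int(rows.size),
            centroid=(float(rows.mean()), float(cols.mean())),
            bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
        )


@dataclass
class Contour:
    """Ordered closed chain of (row, col) border pixels; consecutive points 8-adjacent."""

    points: np.ndarray  # (n, 2) int array


def isolate_cc(
    cmap,
    img: np.ndarray,
    min_area_frac: float = 0.001,
    tau_frac: float = 0.25,
    anchor_frac: tuple[float, float] = (0.45, 0.5),
) -> CCMask:
    """Select the CC component from a cluster map.

    Parameters
    ----------
    cmap : ClusterMap
        Unsupervised classification of the (normalized) slice.
    img : ndarray
        The normalized intensity image, used to rank classes by brightness.
    min_area_frac : float
        Components smaller than this fraction of the image are rejected.
    tau_frac : float
        Width of the Gaussian spatial prior, as a fraction of the image diagonal.
    anchor_frac : (float, float)
        (row, col) of the prior's centre as fractions of the image size; the
        default sits slightly above the image centre.
    """
    labels = np.asarray(cmap.labels)
    img = np.asarray(img, dtype=np.float64)
    if labels.shape != img.shape:
        raise ValueError("cluster map and image shapes differ")
    k = int(cmap.k)
    means = [img[labels == c].mean() if (labels == c).any() else -np.inf for c in range(1, k + 1)]
    cc_class = int(np.argmax(means)) + 1

    binary = labels == cc_class
    opened = ndi.binary_opening(binary, structure=morphology.disk(1).astype(bool))
    comp = measure.label(opened, connectivity=2)
    n_comp = comp.max()
    h, w = img.shape
    min_area = min_area_frac * h * w
    tau = tau_frac * float(np.hypot(h, w))
    anchor = np.array([anchor_frac[0] * h, anchor_frac[1] * w])

    best_id, best_score = 0, -np.inf
    for cid in range(1, n_comp + 1):
        rows, cols = np.nonzero(comp == cid)
        area = rows.size
        if area < min_area:
            continue
        d = np.linalg.norm([rows.mean(), cols.mean()] - anchor)
        score = area * np.exp(-(d * d) / (2.0 * tau * tau))
        if score > best_score:
            best_id, best_score = cid, score
    if best_id == 0:
        raise CCNotFoundError(
            "no component of the brightest class passes the minimal area "
            f"({min_area:.0f} px); CC not found"
        )
    return CCMask.from_mask(comp == best_id)


# Clockwise Moore neighbourhood, starting west.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def border_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of mask pixels with a 4-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    return mask & ~ndi.binary_erosion(mask, structure=cross, border_value=0)


def trace_contour(cc: CCMask | np.ndarray) -> Contour:
    """Moore-neighbour boundary tracing with Jacob's stopping criterion."""
    mask = cc.mask if isinstance(cc, CCMask) else np.asarray(cc, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("contour tracing requires a non-empty 2-D mask")
    rows, cols = np.nonzero(mask)
    if rows.size == 1:
        return Contour(points=np.array([[rows[0], cols[0]]], dtype=int))

    # Uppermost-leftmost foreground pixel; its west neighbour is background.
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = mask.shape

    def is_fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    def step(cur, back_dir):
        """Scan clockwise from the backtrack direction; return (next, new_back_dir)."""
        for s in range(1, 9):
            d = (back_dir + s) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if is_fg(nxt):
                # New backtrack: the last background cell scanned, re-expressed
                # as a direction from the pixel we are stepping onto.
                prev = (cur[0] + _MOORE[(d - 1) % 8][0], cur[1] + _MOORE[(d - 1) % 8][1])
                delta = (prev[0] - nxt[0], prev[1] - nxt[1])
                return nxt, _MOORE.index(delta)
        return None, None  # isolated pixel (cannot happen: handled above)

    # Walk the (pixel, backtrack-direction) state graph until a state repeats:
    # Jacob's criterion (re-entering the start pixel from the same direction)
    # is the usual case; tracking full states also guarantees termination on
    # degenerate geometries.
    state = (start, 0)  # backtrack = west of start, guaranteed background
    seen = {state: 0}
    chain = [start]
    limit = 8 * int(mask.sum()) + 8
    while True:
        nxt, nback = step(*state)
        if nxt is None:
            break
        state = (nxt, nback)
        if state in seen:
            cut = seen[state]
            if cut:  # drop any non-cyclic lead-in (does not occur on simple masks)
                chain = chain[cut:]
            break
        seen[state] = len(chain)
        chain.append(nxt)
        if len(chain) > limit:  # safety net; unreachable on valid masks
            raise RuntimeError("contour tracing failed to terminate")
    if len(chain) > 1 and chain[-1] == chain[0]:
        chain = chain[:-1]
    return Contour(points=np.array(chain, dtype=int))
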