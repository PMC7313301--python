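"""Synthetic midsagittal-like phantoms with exact ground truth.

A phantom slice contains a bright, downward-opening elliptical-annulus arch
(the corpus-callosum surrogate), darker tissue blobs, an optional thin
bright appendage descending from the arch's posterior underside (the fornix
surrogate, same intensity as the arch and 8-adjacent to it but disjoint),
and additive Gaussian noise clipped to [0, 1]. Ground truth comprises the
exact arch mask and a five-parcel labelling by equal arc-length bands along
the arch midline, anterior to posterior — the natural analogue of the
geometric schemes on a curved structure.

The default spec emulates the study conditions this package targets:
256 x 256 slices, a clearly hyperintense CC over grey-matter-like tissue on
a dark background, and mild acquisition noise (intensity separations at
least five noise standard deviations). Everything is deterministic given
the seed. What these phantoms do not emulate: bias fields, partial-volume
averaging, Rician noise statistics, and anatomical shape variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cc_isolation import CCMask
from .parcellation import ParcelMap

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom", "make_plateau_image", "easy_preset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic slice.

    ``arch_center`` / ``arch_radii`` / ``thickness`` default to fractions of
    the image size chosen to mimic CC proportions in a 256 x 256 midsagittal
    slice; ``parcel_offsets`` adds per-parcel intensity deltas to the arch
    (all zeros keeps the arch homogeneous).
    """

    size: tuple[int, int] = (256, 256)
    cc_intensity: float = 0.85
    tissue_intensity: float = 0.45
    background_intensity: float = 0.10
    noise_sigma: float = 0.03
    fornix: bool = True
    arch_center: tuple[int, int] | None = None
    arch_radii: tuple[float, float] | None = None
    thickness: float | None = None
    parcel_offsets: tuple[float, float, float, float, float] = (0.0,) * 5
    seed: int = 0

    def resolved_geometry(self) -> tuple[tuple[int, int], tuple[float, float], float]:
        h, w = self.size
        center = self.arch_center or (round(0.46 * h), w // 2)
        radii = self.arch_radii or (round(0.30 * w), round(0.13 * h))
        thickness = self.thickness if self.thickness is not None else max(3.0, round(0.047 * h))
        return center, (float(radii[0]), float(radii[1])), float(thickness)

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError(f"phantom size must be at least 32x32, got {self.size}")
        for name in ("cc_intensity", "tissue_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if len(self.parcel_offsets) != 5:
            raise ValueError("parcel_offsets must have 5 entries")
        (cr, cc), (a, b), t = self.resolved_geometry()
        if t < 3:
            raise ValueError(f"arch thickness must be >= 3 px, got {t}")
        if (
            cc - (a + t / 2) < 1
            or cc + (a + t / 2) > w - 2
            or cr - (b + t / 2) < 1
            or cr > h - 2
        ):
            raise ValueError("arch does not fit inside the image")


@dataclass
class PhantomBundle:
    image: np.ndarray
    cc_mask: CCMask
    parcels_gt: ParcelMap
    fornix_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def easy_preset(seed: int = 0, fornix: bool = True) -> PhantomSpec:
    """The default study conditions: well-separated intensities, mild noise."""
    return PhantomSpec(seed=seed, fornix=fornix)


def _arch_masks(spec: PhantomSpec):
    h, w = spec.size
    (cr, ccol), (a, b), t = spec.resolved_geometry()
    rows, cols = np.mgrid[0:h, 0:w]
    u = cols - ccol
    v = cr - rows  # positive above the arch centre row
    a_out, b_out = a + t / 2, b + t / 2
    a_in, b_in = max(a - t / 2, 0.5), max(b - t / 2, 0.5)
    outer = (u / a_out) ** 2 + (v / b_out) ** 2 <= 1.0
    inner = (u / a_in) ** 2 + (v / b_in) ** 2 < 1.0
    cc = outer & ~inner & (v >= 0)
    return cc, (cr, ccol, a, b, t), (u, v)


def _equal_arc_boundaries(a: float, b: float, n_bands: int = 5, n_grid: int = 4096):
    """Angular cut positions (measured from the anterior end) splitting the
    upper-half ellipse midline into equal arc-length bands."""
    phi = np.linspace(0.0, np.pi, n_grid + 1)
    ds = np.hypot(a * np.sin(phi), b * np.cos(phi))
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(phi))])
    total = s[-1]
    targets = total * np.arange(1, n_bands) / n_bands
    return np.interp(targets, s, phi), total


def make_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Render one phantom bundle; bit-identical for identical specs."""
    if spec is None:
        spec = PhantomSpec()
    h, w = spec.size
    cc, (cr, ccol, a, b, t), (u, v) = _arch_masks(spec)

    # Tissue blobs: a large lower mass and a smaller upper-anterior one.
    rows, cols = np.mgrid[0:h, 0:w]
    b1r, b1c = cr + round(0.29 * h), ccol
    blob1 = ((rows - b1r) / (0.10 * h)) ** 2 + ((cols - b1c) / (0.22 * w)) ** 2 <= 1.0
    b2r, b2c = round(0.16 * h), ccol - round(0.23 * w)
    blob2 = ((rows - b2r) / (0.055 * h)) ** 2 + ((cols - b2c) / (0.08 * w)) ** 2 <= 1.0
    tissue = (blob1 | blob2) & ~cc

    # Fornix surrogate: thin bright strip hanging from the posterior underside.
    fornix = np.zeros((h, w), dtype=bool)
    if spec.fornix:
        c0 = int(ccol + round(0.35 * a))
        length = max(4, round(0.11 * h))
        for col in (c0, c0 + 1):
            if not 0 <= col < w:
                continue
            in_col = np.nonzero(cc[:, col])[0]
            if in_col.size == 0:
                continue
            start = int(in_col.max()) + 1
            stop = min(start + length, h)
            fornix[start:stop, col] = True
        fornix &= ~cc & ~tissue

    # Ground-truth parcels: equal arc-length bands anterior -> posterior.
    bounds, _ = _equal_arc_boundaries(a, b)
    ccr, cccs = np.nonzero(cc)
    theta = np.arctan2(v[ccr, cccs] / b, u[ccr, cccs] / a)
    phi = np.pi - np.clip(theta, 0.0, np.pi)  # 0 at the anterior end
    band = 1 + (phi[:, None] >= bounds[None, :] - 1e-12).sum(axis=1)
    parcels = np.zeros((h, w), dtype=np.int64)
    parcels[ccr, cccs] = band

    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    img[tissue] = spec.tissue_intensity
    img[cc] = spec.cc_intensity
    offsets = np.asarray(spec.parcel_offsets)
    if np.any(offsets != 0):
        img[ccr, cccs] = spec.cc_intensity + offsets[band - 1]
    img[fornix] = spec.cc_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    return PhantomBundle(
        image=img,
        cc_mask=CCMask.from_mask(cc),
        parcels_gt=ParcelMap(labels=parcels, scheme="phantom_gt", axis=(0.0, 1.0)),
        fornix_mask=fornix,
        spec=spec,
    )


def make_plateau_image(
    levels,
    size: tuple[int, int] = (48, 48),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Vertical equal-width intensity bands plus optional Gaussian noise.

    A fixture for class-count selection: the true class count is the number
    of distinct levels.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 intensity levels")
    h, w = size
    if len(levels) > w:
        raise ValueError(f"more levels ({len(levels)}) than columns ({w})")
    img = np.empty((h, w), dtype=np.float64)
    for i, chunk in enumerate(np.array_split(np.arange(w), len(levels))):
        img[:, chunk] = levels[i]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=(h, w))
    return np.clip(img, 0.0, 1.0)
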