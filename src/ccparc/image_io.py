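"""Image and label-map I/O and the shared coordinate conventions.

Every module in this package indexes 2-D arrays as ``(row, col)`` with row 0
at the image top. "Anterior" defaults to smaller column indices; modules that
care expose a flag to flip it. Grayscale images travel as ``float64`` arrays
("GrayImage"); label maps as non-negative integer arrays ("LabelImage") with
0 meaning background.

Supported formats: PNG and TIFF through imageio, single-slice extraction from
NIfTI-1 volumes through nibabel (first array axis taken as sagittal). Label
maps are written as 16-bit PNG so round-trips are lossless for labels < 2^16.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = [
    "read_gray",
    "write_label_map",
    "read_label_map",
    "normalize_intensity",
    "validate_gray",
]

#: Rec. 709 luma weights used to collapse RGB inputs to one channel.
_LUMA = np.array([0.2125, 0.7154, 0.0721])

MIN_SIDE = 8


def _is_nifti(path: os.PathLike | str) -> bool:
    name = str(path).lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def validate_gray(img: np.ndarray, min_side: int = MIN_SIDE) -> np.ndarray:
    """Check GrayImage invariants: 2-D, finite, at least ``min_side`` per axis."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {img.shape}")
    if img.shape[0] < min_side or img.shape[1] < min_side:
        raise ValueError(
            f"image too small: {img.shape}, need at least {min_side}x{min_side}"
        )
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite intensities")
    return img


def read_gray(path: os.PathLike | str, slice_index: int | None = None) -> np.ndarray:
    """Read a 2-D grayscale image (PNG/TIFF) or one sagittal slice of a NIfTI volume.

    Multi-channel inputs are reduced to luminance; intensities are preserved
    without rescaling. For 3-D NIfTI volumes ``slice_index`` selects the slice
    along the first (sagittal) axis and is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        vol = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64))
        if vol.ndim == 2:
            img = vol
        elif vol.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"volume input requires a sagittal slice index: {path}"
                )
            if not 0 <= int(slice_index) < vol.shape[0]:
                raise ValueError(
                    f"slice index {slice_index} out of range for volume of "
                    f"shape {vol.shape}: {path}"
                )
            img = vol[int(slice_index)]
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}: {path}")
    else:
        import imageio.v3 as iio

        try:
            arr = np.asarray(iio.imread(path), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
            raise IOError(f"cannot read image: {path}") from exc
        if arr.ndim == 3:
            arr = arr[..., :3] @ _LUMA
        img = arr
    return validate_gray(img)


def write_label_map(labels: np.ndarray, path: os.PathLike | str) -> None:
    """Write a label map as 16-bit PNG. Round-trips losslessly for labels < 2^16."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise ValueError("label map must contain integers")
        labels = labels.astype(np.int64)
    if labels.min() < 0 or labels.max() >= 2**16:
        raise ValueError(
            f"labels out of 16-bit unsigned range: [{labels.min()}, {labels.max()}]"
        )
    import imageio.v3 as iio

    try:
        iio.imwrite(Path(path), labels.astype(np.uint16))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write label map: {path}") from exc


def read_label_map(path: os.PathLike | str) -> np.ndarray:
    """Read back a label map written by :func:`write_label_map`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read label map: no such file: {path}")
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read label map: {path}") from exc
    if arr.ndim != 2:
        raise ValueError(f"label map file is not single-channel 2-D: {path}")
    return arr.astype(np.int64)


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Affine min-max rescaling to [0, 1]; constant images map to all zeros.

    Idempotent on its own output: a [0,1] image with min 0 and max 1 is
    returned unchanged bit-for-bit.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("cannot normalize non-finite intensities")
    lo = img.min()
    span = img.max() - lo
    if span == 0:
        return np.zeros_like(img)
    return (img - lo) / span
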