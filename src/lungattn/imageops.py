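"""Image preprocessing and prediction post-processing.

Preprocessing resizes to the network's working resolution and applies
global histogram equalization (a 256-bin CDF remap); intensities are
deliberately *not* mean/std normalized. Post-processing binarizes the
probability map and keeps only the largest connected components — two
by default, one per lung field.
"""

from __future__ import annotations

import numpy as np
from skimage import measure, transform

from .errors import DimensionError, ValidationError

__all__ = [
    "preprocess",
    "equalize_histogram",
    "resize_image",
    "resize_mask",
    "binarize",
    "keep_largest_components",
    "keep_two_largest",
    "read_gray_png",
    "write_gray_png",
    "read_mask_png",
    "write_mask_png",
]


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise ValidationError("empty image")
    if img.ndim != 2:
        raise DimensionError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global 256-bin histogram equalization of an 8-bit image.

    Each level v is remapped to floor(cdf(v) * 255 / N), a monotone
    non-decreasing map; a constant image maps to the constant 255.
    """
    img = _check_gray(img).astype(np.int64)
    if img.min() < 0 or img.max() > 255:
        raise ValidationError("image values must be in [0, 255]")
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    lut = (cdf * 255) // img.size
    return lut[img].astype(np.uint8)


def resize_image(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an 8-bit image; identity when already at target size."""
    img = _check_gray(img)
    if img.shape == tuple(target):
        return img.astype(np.uint8).copy()
    out = transform.resize(
        img.astype(np.float64), target, order=1, mode="edge", anti_aliasing=False
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (binarity preserved)."""
    mask = np.asarray(mask)
    if mask.shape == tuple(target):
        return (mask > 0).astype(np.uint8)
    out = transform.resize(
        mask.astype(np.float64), target, order=0, mode="edge", anti_aliasing=False
    )
    return (out > 0.5).astype(np.uint8)


def preprocess(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Resize then histogram-equalize (equalization statistics at working size)."""
    return equalize_histogram(resize_image(img, target))


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where prob strictly exceeds the threshold, else 0."""
    prob = np.asarray(prob, dtype=np.float64)
    if not np.all(np.isfinite(prob)):
        raise ValidationError("probability map contains non-finite values")
    if prob.size and (prob.min() < 0.0 or prob.max() > 1.0):
        raise ValidationError("probability map values must lie in [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return (prob > threshold).astype(np.uint8)


def keep_largest_components(
    mask: np.ndarray, n_keep: int = 2, connectivity: int = 2
) -> np.ndarray:
    """Keep the ``n_keep`` largest connected components of a binary mask.

    8-connectivity by default (``connectivity=2`` in scikit-image
    convention). Area ties are broken deterministically in favour of the
    component whose first pixel comes earliest in row-major order, which
    is the label order scikit-image assigns. Never adds a pixel and is
    idempotent.
    """
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    labels, n = measure.label(mask, connectivity=connectivity, return_num=True)
    if n <= n_keep:
        return mask
    areas = np.bincount(labels.ravel())[1:]  # skip background
    # stable sort by descending area keeps earlier labels on ties
    order = np.argsort(-areas, kind="stable")[:n_keep] + 1
    return np.isin(labels, order).astype(np.uint8)


def keep_two_largest(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Remove everything but the two largest areas (one per lung field)."""
    return keep_largest_components(mask, n_keep=2, connectivity=connectivity)


# ---------------------------------------------------------------------------
# PNG I/O (masks stored as {0, 255})


def read_gray_png(path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def write_gray_png(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_mask_png(path) -> np.ndarray:
    return (read_gray_png(path) > 127).astype(np.uint8)


def write_mask_png(path, mask: np.ndarray) -> None:
    write_gray_png(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
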