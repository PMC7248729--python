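"""Unsupervised foreground detection by inter-class-variance thresholding.

Feces objects have no fixed shape or location, which rules out shape- and
location-based detectors and makes bounding-box labeling for a learned
detector impractical.  Segmentation here is therefore training-free: the
saturation channel of the image is quantized to 8 bits and thresholded at
the gray level that maximizes the inter-class variance

    g(t) = w0 (mu0 - mu)^2 + w1 (mu1 - mu)^2

where w0, w1 are the pixel proportions of the two classes induced by
threshold t, mu0, mu1 their mean gray levels, and mu = w0 mu0 + w1 mu1 the
global mean (Otsu's criterion).  Saturation is the discriminative channel
because the object is chromatic while the acquisition background is
near-achromatic, and because saturation — being a ratio of channel
differences — is largely invariant to the global illumination level, the
segmentation itself is illumination-insensitive.  Mask stability across
illumination scales is quantified with the normalized Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .colorspace import saturation_map
from .errors import DegenerateHistogramError, DegenerateMaskError, InvalidInputError

__all__ = [
    "ThresholdResult",
    "otsu_threshold",
    "threshold_curve",
    "segment",
    "postprocess_mask",
    "normalized_hamming",
    "apply_mask",
    "crop_to_mask",
]

# 8-connectivity for component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the exhaustive threshold search.

    ``threshold`` is the gray level t* maximizing g; pixels > t* form the
    foreground class, pixels <= t* the background class.  ``class_means``
    and ``class_weights`` are (foreground, background) pairs at t*;
    weights sum to 1 exactly.
    """

    threshold: int
    inter_variance: float
    class_means: tuple[float, float]
    class_weights: tuple[float, float]


def otsu_threshold(gray: np.ndarray) -> ThresholdResult:
    """Exhaustive search for the threshold maximizing inter-class variance.

    ``gray`` must be quantized to integer levels in [0, 255].  Every
    candidate threshold t in 0..254 that leaves both classes non-empty is
    evaluated; ties in g are broken toward the smallest t.  A constant map
    has g(t) = 0 for every t and raises
    :class:`~stooltrait.errors.DegenerateHistogramError`.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise InvalidInputError("empty grayscale map")
    if gray.min() < 0 or gray.max() > 255:
        raise InvalidInputError("gray levels must lie in [0, 255]")
    levels = gray.reshape(-1).astype(np.int64)
    hist = np.bincount(levels, minlength=256).astype(np.float64)
    total = levels.size
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant grayscale map: inter-class variance is 0 for every threshold"
        )

    # cumulative pixel counts and gray-level sums up to and including t
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * np.arange(256))
    n_low = csum[:-1]            # pixels <= t, t = 0..254
    n_high = total - n_low       # pixels > t
    valid = (n_low > 0) & (n_high > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        mu_low = cmoment[:-1] / n_low
        mu_high = (cmoment[-1] - cmoment[:-1]) / n_high
    w_low = n_low / total
    w_high = n_high / total
    mu = cmoment[-1] / total
    g = w_high * (mu_high - mu) ** 2 + w_low * (mu_low - mu) ** 2
    g[~valid] = -np.inf

    t = int(np.argmax(g))  # argmax returns the first (smallest) maximizer
    return ThresholdResult(
        threshold=t,
        inter_variance=float(g[t]),
        class_means=(float(mu_high[t]), float(mu_low[t])),
        class_weights=(float(w_high[t]), float(w_low[t])),
    )


def threshold_curve(gray: np.ndarray):
    """Inter-class variance g at every candidate threshold, for inspection.

    Returns a DataFrame with columns (threshold, inter_variance); thresholds
    that leave a class empty carry NaN.  Dump to CSV to eyeball where the
    search landed.
    """
    import pandas as pd

    flat = np.asarray(gray, dtype=np.float64).reshape(-1)
    rows = []
    for t in range(255):
        low, high = flat[flat <= t], flat[flat > t]
        if low.size == 0 or high.size == 0:
            rows.append((t, np.nan))
            continue
        w0, w1 = high.size / flat.size, low.size / flat.size
        mu0, mu1 = float(high.mean()), float(low.mean())
        mu = w0 * mu0 + w1 * mu1
        rows.append((t, w0 * (mu0 - mu) ** 2 + w1 * (mu1 - mu) ** 2))
    return pd.DataFrame(rows, columns=["threshold", "inter_variance"])


def postprocess_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its holes.

    Guards the segmentation against speckle from sensor noise; a no-op on
    clean single-blob masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def segment(img: np.ndarray, postprocess: bool = True) -> np.ndarray:
    """Detect the foreground object of ``img`` as a boolean mask.

    The saturation map is quantized to round(s * 255), thresholded by
    :func:`otsu_threshold`, and the higher-saturation class (> t*) is taken
    as foreground — the object is chromatic, the background achromatic.
    With ``postprocess`` the largest connected component is kept and holes
    are filled.
    """
    s = saturation_map(img)
    q = np.floor(s * 255.0 + 0.5).astype(np.uint8)
    result = otsu_threshold(q)
    mask = q > result.threshold
    if postprocess:
        mask = postprocess_mask(mask)
    return mask


def normalized_hamming(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pixels at which two equal-sized binary masks disagree.

    A metric on masks of fixed size: 0 for identical masks, 1 for
    complementary ones.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidInputError("empty masks")
    return float(np.mean(a != b))


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels, leaving foreground pixels unchanged."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    if not mask.any():
        raise DegenerateMaskError("mask has no foreground pixels")
    return np.where(mask[..., None], img, 0).astype(img.dtype)


def crop_to_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Crop ``img`` to the bounding box of the mask's foreground."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateMaskError("mask has no foreground pixels")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
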