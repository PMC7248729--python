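"""RGB -> HSV conversion with the value channel kept on the 0-255 scale.

The trait-recognition pipeline works in HSV because, of the three HSV
channels, only *value* responds to a global change of illumination level:
hue and saturation are ratios of channel differences and are invariant under
multiplying all of (r, g, b) by a constant.  Illumination normalization
therefore operates on the value channel, while object detection operates on
the saturation channel (a chromatic object on a near-achromatic background
is a bimodal saturation map).

Conventions:

* hue in degrees, ``[0, 360)``; achromatic pixels (max == min) get hue 0
* saturation in ``[0, 1]``; black pixels (max == 0) get saturation 0
* value equals ``max(r, g, b)`` per pixel, i.e. it stays on the native
  0-255 integer scale rather than being rescaled to ``[0, 1]``

All computation is floating point; nothing is quantized here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["HSVImage", "validate_color_image", "rgb_to_hsv", "saturation_map"]


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel hue/saturation/value planes of one color image.

    Attributes
    ----------
    hue : (H, W) float array, degrees in [0, 360)
    saturation : (H, W) float array in [0, 1]
    value : (H, W) float array in [0, 255]; equals max(r, g, b) per pixel
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


def validate_color_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid H x W x 3 RGB image with channels in [0, 255].

    Returns the image as a float64 array (integer inputs are accepted and
    promoted; no rounding occurs).  Raises :class:`InvalidInputError` on an
    empty image, a wrong number of channels, or out-of-range values.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(
            f"expected an H x W x 3 RGB image, got shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1 or img.size == 0:
        raise InvalidInputError("empty image")
    f = img.astype(np.float64, copy=False)
    if f.min() < 0 or f.max() > 255:
        raise InvalidInputError("channel values must lie in [0, 255]")
    return f


def rgb_to_hsv(img: np.ndarray) -> HSVImage:
    """Convert an RGB image to HSV with value = max(r, g, b).

    Hue is computed branchwise from which channel attains the maximum:

    * max == min          -> h = 0 (achromatic)
    * max == r, g >= b    -> h = 60 (g - b) / (max - min)
    * max == r, g <  b    -> h = 60 (g - b) / (max - min) + 360
    * max == g            -> h = 60 (b - r) / (max - min) + 120
    * max == b            -> h = 60 (r - g) / (max - min) + 240

    Saturation is (max - min) / max, defined as 0 where max == 0.  Where two
    channels tie for the maximum the branches agree, so branch order does
    not affect the result.
    """
    f = validate_color_image(img)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc

    with np.errstate(divide="ignore", invalid="ignore"):
        hue = np.select(
            [
                delta == 0,
                (maxc == r) & (g >= b),
                (maxc == r) & (g < b),
                maxc == g,
                maxc == b,
            ],
            [
                0.0,
                60.0 * (g - b) / delta,
                60.0 * (g - b) / delta + 360.0,
                60.0 * (b - r) / delta + 120.0,
                60.0 * (r - g) / delta + 240.0,
            ],
        )
        saturation = np.where(maxc == 0, 0.0, delta / np.where(maxc == 0, 1.0, maxc))

    return HSVImage(hue=hue, saturation=saturation, value=maxc)


def saturation_map(img: np.ndarray) -> np.ndarray:
    """Saturation plane of ``img`` as an (H, W) float array in [0, 1].

    This is the grayscale map the detection stage thresholds: feces objects
    are chromatic (high saturation) while the acquisition background is
    near-achromatic (saturation close to 0).
    """
    return rgb_to_hsv(img).saturation
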