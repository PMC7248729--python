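"""Illumination normalization against a corpus-level background reference.

Acquisition rigs in different hospitals run at different global illumination
levels, and a classifier trained at one level degrades when tested at
another.  Because the imaging background is approximately uniform, its mean
value-channel level is a usable proxy for the illumination level of a whole
image.  The scheme is:

1. during training, average the background value level over all training
   images to obtain the *standard illumination value* ``v_s``;
2. at test time, measure the test image's background value level ``v_t``
   and multiply all three RGB channels by a single correction ratio that
   maps ``v_t`` onto ``v_s``.

Multiplying all channels by the same factor preserves hue and saturation
(up to clipping and integer rounding), so the correction changes only the
brightness of the scene.

``simulate_illumination`` applies the inverse operation — a global
brightness scale ``k`` — and exists to generate test conditions for
robustness experiments, emulating acquisition under brighter or darker
astigmatic lighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colorspace import rgb_to_hsv, validate_color_image
from .errors import DegenerateIlluminationError, DegenerateMaskError, InvalidInputError

__all__ = [
    "IlluminationReference",
    "background_mean_value",
    "border_background_mask",
    "compute_reference",
    "normalize_illumination",
    "simulate_illumination",
]


@dataclass(frozen=True)
class IlluminationReference:
    """Standard illumination value of a training corpus.

    Attributes
    ----------
    v_s : mean background value-channel level, in (0, 255]
    n_images : number of training images that contributed
    estimator : how background pixels were identified ("segmentation"
        complement or fixed "border" frame)
    """

    v_s: float
    n_images: int
    estimator: str = "segmentation"

    def __post_init__(self) -> None:
        if not (0 < self.v_s <= 255):
            raise InvalidInputError(f"v_s must be in (0, 255], got {self.v_s}")
        if self.n_images < 1:
            raise InvalidInputError("n_images must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"v_s": self.v_s, "n_images": self.n_images, "estimator": self.estimator}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IlluminationReference":
        d = json.loads(Path(path).read_text())
        return cls(v_s=d["v_s"], n_images=d["n_images"], estimator=d.get("estimator", "segmentation"))


def _round_half_up_u8(f: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] then round half-up to uint8."""
    return np.floor(np.clip(f, 0, 255) + 0.5).astype(np.uint8)


def background_mean_value(img: np.ndarray, background: np.ndarray) -> float:
    """Mean value-channel level over the background pixels of ``img``.

    ``background`` is a boolean mask, True on background.  This quantity is
    the per-image illumination estimate: ``v_i`` for a training image,
    ``v_t`` for a test image.
    """
    f = validate_color_image(img)
    background = np.asarray(background, dtype=bool)
    if background.shape != f.shape[:2]:
        raise InvalidInputError(
            f"mask shape {background.shape} does not match image {f.shape[:2]}"
        )
    if not background.any():
        raise DegenerateMaskError("background mask has no pixels")
    value = rgb_to_hsv(f).value
    return float(value[background].mean())


def border_background_mask(shape: tuple[int, int], frac: float = 0.05) -> np.ndarray:
    """Fallback background estimator: a frame of the outermost rows/columns.

    Used when no segmentation mask is available.  ``frac`` is the fraction
    of rows/columns on each side included in the frame (at least 1 pixel).
    """
    h, w = shape
    bh = max(1, int(round(h * frac)))
    bw = max(1, int(round(w * frac)))
    mask = np.zeros((h, w), dtype=bool)
    mask[:bh, :] = mask[-bh:, :] = True
    mask[:, :bw] = mask[:, -bw:] = True
    return mask


def compute_reference(
    images: list[np.ndarray],
    backgrounds: list[np.ndarray],
    estimator: str = "segmentation",
) -> IlluminationReference:
    """Average per-image background value levels into a corpus reference.

    ``v_s = (1/n) sum_i v_i`` where ``v_i`` is :func:`background_mean_value`
    of the i-th training image.
    """
    if len(images) == 0:
        raise InvalidInputError("need at least one training image")
    if len(images) != len(backgrounds):
        raise InvalidInputError("images and backgrounds must be aligned")
    v = [background_mean_value(img, bg) for img, bg in zip(images, backgrounds)]
    return IlluminationReference(v_s=float(np.mean(v)), n_images=len(v), estimator=estimator)


def normalize_illumination(
    img: np.ndarray,
    v_t: float,
    ref: IlluminationReference,
    ratio_convention: str = "as_intended",
) -> np.ndarray:
    """Rescale all three RGB channels so the background level v_t maps onto v_s.

    With the default ``ratio_convention="as_intended"`` every channel is
    multiplied by ``v_s / v_t``, which carries the test image's background
    level onto the corpus standard (this is the direction that makes
    normalize(simulate(img, k)) a round trip).  ``"as_printed"`` multiplies
    by ``v_t / v_s`` instead, preserving the literal published formula.

    Results are clipped to [0, 255] and rounded half-up to uint8.  Hue is
    preserved for unclipped pixels because the three channels share one
    multiplier.
    """
    f = validate_color_image(img)
    if v_t <= 0:
        raise DegenerateIlluminationError(
            f"background illumination v_t must be positive, got {v_t}"
        )
    if ratio_convention == "as_intended":
        ratio = ref.v_s / v_t
    elif ratio_convention == "as_printed":
        ratio = v_t / ref.v_s
    else:
        raise InvalidInputError(f"unknown ratio_convention {ratio_convention!r}")
    return _round_half_up_u8(f * ratio)


def simulate_illumination(img: np.ndarray, scale: float) -> np.ndarray:
    """Apply a global illumination scale ``k`` to all three channels.

    Emulates acquiring the same scene under brighter (k > 1) or darker
    (k < 1) level-only lighting; the nominal experimental range is
    [0.5, 1.5].  Values clip at 255, so bright scenes saturate at large k.
    """
    f = validate_color_image(img)
    if scale <= 0:
        raise InvalidInputError(f"illumination scale must be positive, got {scale}")
    return _round_half_up_u8(f * scale)
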