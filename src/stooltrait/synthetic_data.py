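"""Synthetic trait-image generator with ground-truth masks.

Real fecal trait datasets are private (hospital data, patient consent), so
every stage of the pipeline is exercised on synthetic images that emulate
the acquisition conditions the pipeline assumes:

* a near-uniform, near-achromatic background (saturation well below 0.1),
* one connected chromatic foreground blob whose color and texture
  statistics differ by trait class,
* an optional global illumination scale in [0.5, 1.5] applied at
  "acquisition" time.

The five class palettes are fictional stand-ins — they are not claimed to
match real fecal appearance.  They give the classifier a learnable 5-way
signal with the same structural role the real classes play: the tar /
loose / paste classes share a brown hue family and are separated mainly by
their value (brightness) level, which is exactly the information a global
illumination shift corrupts, while mucus (green hue, speckled texture) and
watery (low saturation, bright) are separated chromatically.

Blob silhouettes are unions of randomly perturbed ellipses smoothed by
morphological closing, which are generically asymmetric (so the 7-variant
augmentation count holds); the "loose" class instead scatters small lobes
joined by thin bridges so the object stays one connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.draw import line as draw_line
from skimage.morphology import closing, dilation, disk

from .augmentation import TRAIT_CLASSES, SampleRecord, augment, salt_noise
from .errors import InvalidInputError
from .illumination import simulate_illumination

__all__ = ["ClassPalette", "GeneratorConfig", "generate_image", "generate_dataset"]


@dataclass(frozen=True)
class ClassPalette:
    """Foreground color/texture distribution of one trait class.

    hue (degrees), saturation in [0, 1] and value in [0, 255] are the
    centers of per-image distributions; ``value_texture`` is the amplitude
    of per-pixel value noise and ``texture_smooth`` its Gaussian
    correlation length in pixels (0 = white-noise speckle).
    """

    hue: float
    saturation: float
    value: float
    hue_jitter: float = 6.0
    saturation_jitter: float = 0.04
    value_jitter: float = 8.0
    value_texture: float = 8.0
    texture_smooth: float = 3.0
    fragmented: bool = False


_DEFAULT_PALETTES: dict[str, ClassPalette] = {
    # brown-family classes: identical hue/saturation distributions, separated
    # ONLY by value level — the cue a global illumination shift corrupts
    "tar": ClassPalette(hue=25, saturation=0.72, value=45,
                        hue_jitter=8.0, value_texture=6),
    "loose": ClassPalette(hue=25, saturation=0.72, value=95,
                          hue_jitter=8.0, fragmented=True),
    "paste": ClassPalette(hue=25, saturation=0.72, value=145,
                          hue_jitter=8.0, value_texture=8),
    # chromatically distinct classes
    "mucus": ClassPalette(hue=120, saturation=0.60, value=150,
                          value_texture=30, texture_smooth=0.0),
    "watery": ClassPalette(hue=50, saturation=0.35, value=200,
                           value_texture=5, texture_smooth=4.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-condition parameters of the generator.

    ``background_value`` is the mean gray level of the near-uniform
    background (its per-pixel jitter and slight chroma keep the background
    realistic while its saturation stays an order of magnitude below any
    foreground class).  240x240 square frames make 90-degree rotations
    lossless for the augmentation protocol.
    """

    image_size: tuple[int, int] = (240, 240)
    background_value: float = 160.0
    background_level_jitter: float = 20.0
    background_jitter: float = 3.0
    background_chroma: float = 4.0
    background_texture: float = 20.0
    background_texture_smooth: float = 15.0
    class_palettes: dict[str, ClassPalette] = field(
        default_factory=lambda: dict(_DEFAULT_PALETTES)
    )
    illumination_scales: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        missing = set(TRAIT_CLASSES) - set(self.class_palettes)
        if missing:
            raise InvalidInputError(f"palettes missing for classes: {sorted(missing)}")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  amp: float, smooth: float) -> np.ndarray:
    """Zero-mean noise field of std ~amp, optionally spatially correlated."""
    if amp <= 0:
        return np.zeros(shape)
    noise = rng.normal(0.0, 1.0, size=shape)
    if smooth > 0:
        noise = ndimage.gaussian_filter(noise, smooth)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return amp * noise


def _blob_mask(rng: np.random.Generator, size: tuple[int, int],
               fragmented: bool) -> np.ndarray:
    """One connected, generically asymmetric silhouette."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(8):  # retry on degenerate draws
        mask = np.zeros(size, dtype=bool)
        if fragmented:
            n_lobes = int(rng.integers(4, 7))
            centers = []
            for _ in range(n_lobes):
                cy = h / 2 + rng.uniform(-0.22, 0.22) * h
                cx = w / 2 + rng.uniform(-0.22, 0.22) * w
                r = rng.uniform(0.06, 0.10) * min(h, w)
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
                centers.append((int(cy), int(cx)))
            # thin bridges keep the fragments one connected component
            for (y0, x0), (y1, x1) in zip(centers, centers[1:]):
                rr, cc = draw_line(y0, x0, y1, x1)
                bridge = np.zeros(size, dtype=bool)
                bridge[rr, cc] = True
                mask |= dilation(bridge, disk(2))
        else:
            for _ in range(int(rng.integers(3, 6))):
                cy = h / 2 + rng.uniform(-0.14, 0.14) * h
                cx = w / 2 + rng.uniform(-0.14, 0.14) * w
                a = rng.uniform(0.10, 0.20) * h
                b = rng.uniform(0.10, 0.20) * w
                theta = rng.uniform(0, np.pi)
                u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
                v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
                mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask = closing(mask, disk(5))
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        if n >= 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        if mask.mean() >= 0.02:
            return mask
    raise RuntimeError("failed to draw a usable blob silhouette")


def generate_image(
    label: str,
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
    illumination_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one labeled image; returns (uint8 RGB image, ground-truth mask).

    Deterministic given the seed.  The illumination scale multiplies all
    channels after compositing, emulating acquisition under a different
    lighting level.
    """
    cfg = cfg or GeneratorConfig()
    if label not in cfg.class_palettes:
        raise InvalidInputError(f"unknown label {label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = cfg.image_size
    pal = cfg.class_palettes[label]

    # near-achromatic background: a per-image base level (tray albedo varies
    # between acquisitions, which is why the corpus reference averages
    # per-image background means), per-pixel jitter, and low-frequency value
    # blotches (stains / soft shadows).  The blotches average to zero, so
    # the background *mean* stays a precise per-image anchor while local
    # background appearance is a genuine disturbance.
    level = cfg.background_value + rng.uniform(
        -cfg.background_level_jitter, cfg.background_level_jitter
    )
    gray = (
        rng.normal(level, cfg.background_jitter, size=(h, w))
        + _smooth_noise(rng, (h, w), cfg.background_texture,
                        cfg.background_texture_smooth)
    )
    bg = gray[..., None] + rng.uniform(
        -cfg.background_chroma, cfg.background_chroma, size=(h, w, 3)
    )

    mask = _blob_mask(rng, (h, w), pal.fragmented)

    # per-image color draw + per-pixel texture, in HSV
    hue = (pal.hue + rng.normal(0, pal.hue_jitter)
           + _smooth_noise(rng, (h, w), 3.0, 2.0)) % 360.0
    sat = np.clip(
        pal.saturation + rng.normal(0, pal.saturation_jitter)
        + _smooth_noise(rng, (h, w), 0.03, 2.0), 0.05, 1.0,
    )
    val = np.clip(
        pal.value + rng.normal(0, pal.value_jitter)
        + _smooth_noise(rng, (h, w), pal.value_texture, pal.texture_smooth), 5, 255,
    )
    fg = hsv2rgb(np.stack([hue / 360.0, sat, val / 255.0], axis=-1)) * 255.0

    img = np.where(mask[..., None], fg, bg)
    img = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)
    if illumination_scale != 1.0:
        img = simulate_illumination(img, illumination_scale)
    return img, mask


def generate_dataset(
    n_per_class: int,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    augment_protocol: bool = False,
    noise_sigma: float = 0.0,
    noise_copies: int = 0,
    illumination_scale: float = 1.0,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Generate a balanced 5-class dataset of originals (plus optional variants).

    With ``augment_protocol`` each original gains its surviving dihedral
    variants (7 for asymmetric silhouettes); with ``noise_copies > 0`` each
    record then gains that many Gaussian-noise-salted copies of std
    ``noise_sigma``, which share their base record's shape group.  Returns
    the records and a manifest DataFrame.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    cfg = cfg or GeneratorConfig()
    records: list[SampleRecord] = []
    for ci, label in enumerate(TRAIT_CLASSES):
        for i in range(n_per_class):
            child = np.random.SeedSequence([seed, ci, i])
            rng = np.random.default_rng(child)
            img, mask = generate_image(
                label, cfg, seed=rng, illumination_scale=illumination_scale
            )
            rec = SampleRecord(
                image=img, label=label, origin_id=f"{label}-{i:04d}",
                mask=mask, illumination_scale=illumination_scale,
            )
            base = [rec] + (augment(rec) if augment_protocol else [])
            records.extend(base)
            if noise_copies > 0:
                noise_rng = np.random.default_rng(np.random.SeedSequence([seed, ci, i, 1]))
                for b in base:
                    for _ in range(noise_copies):
                        records.append(
                            salt_noise(b, noise_sigma, int(noise_rng.integers(2**31)))
                        )
    manifest = pd.DataFrame(
        {
            "path": [r.path for r in records],
            "label": [r.label for r in records],
            "origin_id": [r.origin_id for r in records],
            "transform_id": [r.transform_id for r in records],
            "noise_seed": [r.noise_seed for r in records],
            "illumination_scale": [r.illumination_scale for r in records],
        }
    )
    return records, manifest
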