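"""Dataset augmentation protocol: dihedral variants, noise salting, group split.

Each original image is rotated three times (90, 180, 270 degrees) and
mirrored, and the three rotations of the mirror are added, giving up to 7
variants; any variant whose foreground silhouette duplicates an earlier
variant's is deleted, so a generic asymmetric object yields exactly 7 while
symmetric objects yield fewer.  Augmented images are then salted with
Gaussian noise.  Noise-salted copies share the silhouette of their base
variant, so all records with the same (origin, transform) pair form one
*shape group*; the train/test split assigns whole shape groups to one side
only, preventing the classifier from recognizing silhouettes it saw in
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CannotSplitError, InvalidInputError

__all__ = [
    "TRAIT_CLASSES",
    "TRANSFORMS",
    "SampleRecord",
    "apply_transform",
    "shape_duplicate",
    "augment",
    "salt_noise",
    "group_split",
]

#: The five macroscopic trait classes, in canonical label-index order.
TRAIT_CLASSES = ("tar", "paste", "mucus", "watery", "loose")

#: Dihedral-variant identifiers, in the order augment() generates them.
TRANSFORMS = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "flip",
    "flip+rot90",
    "flip+rot180",
    "flip+rot270",
)


@dataclass
class SampleRecord:
    """One labeled image with its augmentation provenance.

    ``mask`` is the foreground silhouette (ground truth from the generator
    or the detection stage's segmentation); augmentation needs it for shape
    deduplication.  ``(origin_id, transform_id)`` keys the shape group.
    """

    image: np.ndarray
    label: str
    origin_id: str
    transform_id: str = "identity"
    noise_seed: int | None = None
    mask: np.ndarray | None = None
    illumination_scale: float = 1.0
    path: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in TRAIT_CLASSES:
            raise InvalidInputError(
                f"label {self.label!r} is not one of {TRAIT_CLASSES}"
            )
        if self.transform_id not in TRANSFORMS:
            raise InvalidInputError(f"unknown transform_id {self.transform_id!r}")

    @property
    def shape_group(self) -> tuple[str, str]:
        return (self.origin_id, self.transform_id)

    @property
    def label_index(self) -> int:
        return TRAIT_CLASSES.index(self.label)


def apply_transform(arr: np.ndarray, transform_id: str) -> np.ndarray:
    """Apply one of the 8 dihedral transforms to an image or mask.

    Rotations are multiples of 90 degrees (the only lossless rotations on a
    pixel grid); "flip" is a horizontal mirror, applied before any rotation.
    """
    if transform_id not in TRANSFORMS:
        raise InvalidInputError(f"unknown transform_id {transform_id!r}")
    out = arr
    if transform_id.startswith("flip"):
        out = np.fliplr(out)
    if "rot90" in transform_id:
        out = np.rot90(out, 1)
    elif "rot180" in transform_id:
        out = np.rot90(out, 2)
    elif "rot270" in transform_id:
        out = np.rot90(out, 3)
    return np.ascontiguousarray(out)


def shape_duplicate(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two silhouette masks are pixel-identical.

    Masks of different dimensions (rotations of a non-square frame) are
    never duplicates.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return a.shape == b.shape and bool(np.array_equal(a, b))


def augment(record: SampleRecord) -> list[SampleRecord]:
    """Generate the surviving dihedral variants of an original image.

    The 7 candidates (rot90/180/270, flip, flip+rot90/180/270) are produced
    in that fixed order; a candidate is deleted when its silhouette
    duplicates the original's or an earlier surviving candidate's.  Only
    originals may be augmented, and the record must carry a mask.
    """
    if record.transform_id != "identity":
        raise InvalidInputError("only original (identity) records can be augmented")
    if record.mask is None:
        raise InvalidInputError("augmentation needs the record's silhouette mask")

    seen = [np.asarray(record.mask, dtype=bool)]
    out: list[SampleRecord] = []
    for tid in TRANSFORMS[1:]:
        m = apply_transform(record.mask, tid).astype(bool)
        if any(shape_duplicate(m, s) for s in seen):
            continue
        seen.append(m)
        out.append(
            replace(
                record,
                image=apply_transform(record.image, tid),
                mask=m,
                transform_id=tid,
                path=None,
            )
        )
    return out


def salt_noise(record: SampleRecord, sigma: float, seed: int) -> SampleRecord:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` per channel.

    Values clip to [0, 255].  The silhouette (shape group) is unchanged —
    noise variants share the shape of their base transform.  sigma is on
    the 0-255 scale; sigma = 0 returns an identical copy.
    """
    if sigma < 0:
        raise InvalidInputError(f"noise sigma must be >= 0, got {sigma}")
    img = np.asarray(record.image, dtype=np.float64)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, sigma, size=img.shape)
    img = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)
    return replace(record, image=img, noise_seed=int(seed), path=None)


def group_split(
    records: list[SampleRecord], train_fraction: float, seed: int
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Split records into train/test with zero shape-group leakage.

    All records sharing (origin_id, transform_id) land on the same side.
    The number of training groups is round(train_fraction * n_groups),
    clamped so both sides are non-empty; group assignment is a deterministic
    function of the seed.
    """
    if not (0 < train_fraction < 1):
        raise InvalidInputError("train_fraction must be strictly between 0 and 1")
    groups: dict[tuple[str, str], list[SampleRecord]] = {}
    for rec in records:
        groups.setdefault(rec.shape_group, []).append(rec)
    keys = sorted(groups)
    if len(keys) < 2:
        raise CannotSplitError(
            f"need at least 2 shape groups to split, got {len(keys)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_train = int(round(train_fraction * len(keys)))
    n_train = min(max(n_train, 1), len(keys) - 1)
    train_keys = {keys[i] for i in order[:n_train]}
    train = [r for k in keys if k in train_keys for r in groups[k]]
    test = [r for k in keys if k not in train_keys for r in groups[k]]
    return train, test
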