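"""End-to-end orchestration: preprocess -> train -> evaluate, plus experiments.

The full pipeline runs three stages on every image: illumination
normalization against the training corpus' background reference, object
detection by saturation thresholding (background zeroed, crop to the
object's bounding box), and classification with the shallow CNN at 60x60.
The mask is computed on the *un-normalized* image — detection is
illumination-insensitive, which breaks the chicken-and-egg between
estimating the background level and finding the background.

The ablation harness trains at a single illumination level and tests at
shifted levels under four preprocessing conditions (neither stage,
detection only, normalization only, both), the experimental design that
shows each stage's contribution to illumination robustness.  The
background level v_t is estimated from the segmentation-mask complement in
every condition that normalizes, so conditions differ only in the stage
under test.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .augmentation import TRAIT_CLASSES, SampleRecord, group_split
from .detection import apply_mask, crop_to_mask, normalized_hamming, segment
from .errors import DegenerateHistogramError, InvalidInputError, StoolTraitError
from .illumination import (
    IlluminationReference,
    background_mean_value,
    border_background_mask,
    compute_reference,
    normalize_illumination,
    simulate_illumination,
)
from .synthetic_data import GeneratorConfig, generate_dataset, generate_image
from .trait_cnn import (
    NetworkConfig,
    TrainConfig,
    build_model,
    evaluate,
    images_to_tensor,
    train,
)

__all__ = [
    "CONDITIONS",
    "preprocess",
    "fit_reference",
    "preprocess_records",
    "run_ablation",
    "hamming_stability_table",
    "depth_sweep",
    "write_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

#: Ablation conditions: (detection on, normalization on)
CONDITIONS: dict[str, tuple[bool, bool]] = {
    "none": (False, False),
    "detection_only": (True, False),
    "normalization_only": (False, True),
    "both": (True, True),
}


def _resize_u8(img: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    out = resize(
        img.astype(np.float64), out_size, preserve_range=True, anti_aliasing=True
    )
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def preprocess(
    img: np.ndarray,
    ref: IlluminationReference | None = None,
    detection: bool = True,
    normalization: bool = True,
    ratio_convention: str = "as_intended",
    out_size: tuple[int, int] = (60, 60),
    mask_postprocess: bool = True,
) -> np.ndarray:
    """Preprocess one image to the network's 60x60 input.

    Stage order: segment -> estimate v_t from the mask complement ->
    normalize illumination -> zero the background -> crop to the bounding
    box -> resize.  Either stage can be toggled off; with both off this is
    a plain resize (the "without preprocessing" condition).
    """
    mask = None
    if detection or normalization:
        try:
            mask = segment(img, postprocess=mask_postprocess)
        except StoolTraitError as e:
            raise type(e)(f"detection stage: {e}") from e
    if normalization:
        if ref is None:
            raise InvalidInputError("illumination normalization needs a reference")
        background = ~mask if (mask is not None and (~mask).any()) else \
            border_background_mask(img.shape[:2])
        v_t = background_mean_value(img, background)
        img = normalize_illumination(img, v_t, ref, ratio_convention)
    if detection:
        img = crop_to_mask(apply_mask(img, mask), mask)
    return _resize_u8(img, out_size)


def fit_reference(images: list[np.ndarray]) -> IlluminationReference:
    """Standard illumination value from training images' backgrounds.

    Background = complement of each image's segmentation mask; images whose
    saturation map is flat (no object found) fall back to a border-frame
    estimate.
    """
    backgrounds = []
    estimator = "segmentation"
    for img in images:
        try:
            mask = segment(img)
            bg = ~mask
            if not bg.any():
                raise DegenerateHistogramError("mask covers the whole frame")
        except StoolTraitError:
            bg = border_background_mask(img.shape[:2])
            estimator = "mixed"
        backgrounds.append(bg)
    return compute_reference(images, backgrounds, estimator=estimator)


def preprocess_records(
    records: list[SampleRecord],
    ref: IlluminationReference | None,
    condition: str = "both",
    out_size: tuple[int, int] = (60, 60),
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess a record list into (X, y) training tensors."""
    if condition not in CONDITIONS:
        raise InvalidInputError(f"unknown condition {condition!r}")
    detection, normalization = CONDITIONS[condition]
    images = [
        preprocess(r.image, ref, detection=detection, normalization=normalization,
                   out_size=out_size)
        for r in records
    ]
    y = np.array([r.label_index for r in records], dtype=int)
    return images_to_tensor(images), y


def run_ablation(
    n_per_class: int = 12,
    conditions: tuple[str, ...] = ("none", "detection_only", "normalization_only", "both"),
    test_scales: tuple[float, ...] = (0.5, 1.5),
    seeds: tuple[int, ...] = (0, 1, 2),
    gen_cfg: GeneratorConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    epochs: int = 8,
    train_fraction: float = 0.75,
    data_seed: int = 0,
) -> pd.DataFrame:
    """Train at illumination 1.0, test at shifted scales, per condition.

    Returns a tidy DataFrame with one row per (condition, scale, seed) and
    the held-out accuracy.  The split respects shape groups; the same data
    and reference are reused across conditions and seeds so only the stage
    under test varies.
    """
    records, _ = generate_dataset(
        n_per_class, gen_cfg, seed=data_seed, augment_protocol=True
    )
    train_recs, test_recs = group_split(records, train_fraction, seed=data_seed)
    ref = fit_reference([r.image for r in train_recs])
    net_cfg = net_cfg or NetworkConfig()
    rows = []
    for condition in conditions:
        x_train, y_train = preprocess_records(train_recs, ref, condition)
        test_sets = {}
        for k in test_scales:
            scaled = [
                SampleRecord(
                    image=simulate_illumination(r.image, k), label=r.label,
                    origin_id=r.origin_id, transform_id=r.transform_id,
                    mask=r.mask, illumination_scale=k,
                )
                for r in test_recs
            ]
            test_sets[k] = preprocess_records(scaled, ref, condition)
        for seed in seeds:
            model = build_model(net_cfg, seed=seed)
            train(
                model, x_train, y_train,
                TrainConfig(epochs=epochs, seed=seed, early_stopping_patience=None),
            )
            for k, (x_test, y_test) in test_sets.items():
                acc, _ = evaluate(model, x_test, y_test)
                rows.append(
                    {"condition": condition, "scale": k, "seed": seed,
                     "accuracy": acc, "n_test": len(y_test)}
                )
                logger.info("ablation %s scale=%.2f seed=%d acc=%.4f",
                            condition, k, seed, acc)
    return pd.DataFrame(rows)


def hamming_stability_table(
    n_per_class: int = 10,
    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.1, 1.2, 1.3, 1.4, 1.5),
    gen_cfg: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mask stability under illumination scaling, per class and scale.

    Each cell is the mean normalized Hamming distance between the mask
    segmented at scale 1.0 and the mask segmented at scale k, over
    ``n_per_class`` synthetic images of that class.  Mirrors the
    segmentation-robustness experiment design: low values everywhere mean
    detection is insensitive to the illumination level.
    """
    gen_cfg = gen_cfg or GeneratorConfig()
    table = {}
    for ci, label in enumerate(TRAIT_CLASSES):
        dists = np.zeros((len(scales), n_per_class))
        for i in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, i]))
            img, _ = generate_image(label, gen_cfg, seed=rng)
            base = segment(img)
            for si, k in enumerate(scales):
                dists[si, i] = normalized_hamming(
                    base, segment(simulate_illumination(img, k))
                )
        table[label] = dists.mean(axis=1)
    return pd.DataFrame(table, index=pd.Index(scales, name="illumination_scale"))


def depth_sweep(
    depths: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    n_per_class: int = 8,
    seeds: tuple[int, ...] = (0,),
    gen_cfg: GeneratorConfig | None = None,
    epochs: int = 6,
    data_seed: int = 0,
) -> pd.DataFrame:
    """Held-out accuracy as a function of network depth.

    Depths below 3 drop conv blocks, above 3 double the filter count layer
    by layer.  Reported, not asserted — the best depth is dataset-dependent.
    """
    records, _ = generate_dataset(
        n_per_class, gen_cfg, seed=data_seed, augment_protocol=True
    )
    train_recs, test_recs = group_split(records, 0.75, seed=data_seed)
    ref = fit_reference([r.image for r in train_recs])
    x_train, y_train = preprocess_records(train_recs, ref, "both")
    x_test, y_test = preprocess_records(test_recs, ref, "both")
    rows = []
    for depth in depths:
        cfg = NetworkConfig(depth=depth)
        for seed in seeds:
            model = build_model(cfg, seed=seed)
            train(model, x_train, y_train,
                  TrainConfig(epochs=epochs, seed=seed, early_stopping_patience=None))
            acc, _ = evaluate(model, x_test, y_test)
            rows.append({"depth": depth, "seed": seed, "accuracy": acc,
                         "parameters": model.parameter_count()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset materialization (PNG directories + CSV manifest)
# ---------------------------------------------------------------------------

def write_dataset(records: list[SampleRecord], outdir: str | Path) -> Path:
    """Write records as PNGs with a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, r in enumerate(records):
        stem = f"{r.origin_id}_{r.transform_id}" + (
            f"_n{r.noise_seed}" if r.noise_seed is not None else ""
        )
        rel = f"images/{i:05d}_{stem}.png"
        iio.imwrite(outdir / rel, r.image)
        mask_rel = None
        if r.mask is not None:
            mask_rel = f"masks/{i:05d}_{stem}.png"
            iio.imwrite(outdir / mask_rel, (r.mask.astype(np.uint8) * 255))
        rows.append(
            {"path": rel, "mask_path": mask_rel, "label": r.label,
             "origin_id": r.origin_id, "transform_id": r.transform_id,
             "noise_seed": r.noise_seed, "illumination_scale": r.illumination_scale}
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[SampleRecord]:
    """Load records from a manifest written by :func:`write_dataset`.

    Images with an alpha channel have it dropped; masks are optional.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records = []
    for row in df.itertuples(index=False):
        img = np.asarray(iio.imread(root / row.path))
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[..., :3]
        mask = None
        if isinstance(getattr(row, "mask_path", None), str):
            mask = np.asarray(iio.imread(root / row.mask_path)) > 127
        noise_seed = getattr(row, "noise_seed", None)
        records.append(
            SampleRecord(
                image=img, label=row.label, origin_id=str(row.origin_id),
                transform_id=row.transform_id,
                noise_seed=None if pd.isna(noise_seed) else int(noise_seed),
                mask=mask,
                illumination_scale=float(getattr(row, "illumination_scale", 1.0)),
                path=str(row.path),
            )
        )
    return records
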