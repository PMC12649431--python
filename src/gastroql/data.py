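"""Loading, normalisation, flip augmentation and hold-out splitting.

Classification datasets follow the one-folder-per-class layout
(``root/<class_name>/*.png|jpg``); segmentation data is a pair of
directories ``images/`` and ``masks/`` with matching file stems.  Images
are resized bilinearly; masks by nearest neighbour so they stay binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LabeledImage",
    "SegPair",
    "DatasetSplit",
    "load_image_dataset",
    "normalize_intensity",
    "augment_flip",
    "holdout_split",
    "load_segmentation_pairs",
    "write_manifest",
]


@dataclass
class LabeledImage:
    """One RGB image with an integer class label.

    ``pixels`` holds raw intensities in [0, 255]; normalisation to [0, 1]
    happens downstream via :func:`normalize_intensity`.
    """

    pixels: np.ndarray  # (H, W, 3) in [0, 255]
    label: int
    source_id: str
    augmented: bool = False


@dataclass
class SegPair:
    """One normalised image with its binary ground-truth mask."""

    image: np.ndarray  # (H, W, C) in [0, 1]
    mask: np.ndarray  # (H, W) in {0, 1}
    source_id: str
    augmented: bool = False


@dataclass
class DatasetSplit:
    train: list
    test: list
    seed: int
    fraction: float


def load_image_dataset(root_dir, size: int, class_names: Sequence[str]) -> list[LabeledImage]:
    """Load a per-class-folder image tree, resized to ``size`` x ``size`` x 3.

    Labels are assigned by the position of each class directory name in
    ``class_names``; a missing or empty class directory is an error.
    """
    root = Path(root_dir)
    records: list[LabeledImage] = []
    for label, name in enumerate(class_names):
        class_dir = root / name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"class directory missing: {class_dir}")
        files = sorted(p for p in class_dir.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise ValueError(f"class directory is empty: {class_dir}")
        for path in files:
            try:
                with Image.open(path) as img:
                    img = img.convert("RGB").resize((size, size), Image.BILINEAR)
                    pixels = np.asarray(img, dtype=np.uint8)
            except Exception as exc:  # noqa: BLE001 - re-raise with the file name
                raise OSError(f"cannot read image file {path}: {exc}") from exc
            records.append(LabeledImage(pixels=pixels, label=label, source_id=path.stem))
    return records


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Rescale intensities from [0, 255] to [0, 1] by dividing by 255."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    return arr / 255.0


def _flip_record(rec, axis: int):
    """Flipped copy of a record; axis 0 = vertical, 1 = horizontal."""
    suffix = "_vflip" if axis == 0 else "_hflip"
    if isinstance(rec, LabeledImage):
        return replace(rec, pixels=np.flip(rec.pixels, axis=axis).copy(),
                       source_id=rec.source_id + suffix, augmented=True)
    if isinstance(rec, SegPair):
        return replace(rec, image=np.flip(rec.image, axis=axis).copy(),
                       mask=np.flip(rec.mask, axis=axis).copy(),
                       source_id=rec.source_id + suffix, augmented=True)
    raise TypeError(f"cannot flip record of type {type(rec).__name__}")


def augment_flip(records: list, seed: int) -> list:
    """Originals plus exactly one flipped copy per original (2x the count).

    The flip axis (horizontal or vertical) is drawn per record from a
    seeded generator; masks are flipped together with their images.
    """
    if not records:
        raise ValueError("augment_flip requires a non-empty record list")
    rng = np.random.default_rng(seed)
    axes = rng.integers(0, 2, size=len(records))
    return list(records) + [_flip_record(r, int(a)) for r, a in zip(records, axes)]


def holdout_split(records: list, fraction: float, seed: int) -> DatasetSplit:
    """Seeded, label-stratified hold-out partition.

    Each class is shuffled and split at ``fraction`` with half-up rounding
    of the train count.  Records without a ``label`` attribute (e.g.
    segmentation pairs) are treated as a single stratum.  A class with
    fewer than two members goes entirely to train, with a warning.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    groups: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(getattr(rec, "label", 0), []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(groups):
        idx = np.array(groups[label])
        if len(idx) < 2:
            warnings.warn(f"class {label} has {len(idx)} member(s); assigned to train",
                          stacklevel=2)
            train_idx.extend(idx.tolist())
            continue
        rng.shuffle(idx)
        n_train = int(np.floor(fraction * len(idx) + 0.5))  # round half-up
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return DatasetSplit(
        train=[records[i] for i in train_idx],
        test=[records[i] for i in test_idx],
        seed=seed,
        fraction=fraction,
    )


def load_segmentation_pairs(images_dir, masks_dir, size: int = 128) -> list[SegPair]:
    """Load matching image/mask files into normalised, binarised pairs.

    Images are bilinearly resized and scaled to [0, 1]; masks are resized
    by nearest neighbour, rescaled to [0, 1] and thresholded at 0.5.
    Unmatched files on either side are an error.
    """
    exts = {".png", ".jpg", ".jpeg"}
    img_files = {p.stem: p for p in Path(images_dir).iterdir() if p.suffix.lower() in exts}
    mask_files = {p.stem: p for p in Path(masks_dir).iterdir() if p.suffix.lower() in exts}
    orphans = sorted(set(img_files) ^ set(mask_files))
    if orphans:
        raise ValueError(f"unmatched image/mask stems: {orphans}")
    pairs: list[SegPair] = []
    for stem in sorted(img_files):
        with Image.open(img_files[stem]) as img:
            img = img.convert("RGB").resize((size, size), Image.BILINEAR)
            image = normalize_intensity(np.asarray(img))
        with Image.open(mask_files[stem]) as msk:
            msk = msk.convert("L").resize((size, size), Image.NEAREST)
            mask = (normalize_intensity(np.asarray(msk)) >= 0.5).astype(np.uint8)
        pairs.append(SegPair(image=image, mask=mask, source_id=stem))
    return pairs


def write_manifest(records: list, split_of: dict[str, str], path,
                   class_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Write a CSV manifest (source_id, label/class_name, split, augmented)."""
    rows = []
    for rec in records:
        label = getattr(rec, "label", None)
        rows.append({
            "source_id": rec.source_id,
            "label": label,
            "class_name": class_names[label] if class_names is not None and label is not None else None,
            "split": split_of.get(rec.source_id, ""),
            "augmented": rec.augmented,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
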