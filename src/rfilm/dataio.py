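"""Image/mask I/O, resizing, and dataset partitioning.

Conventions
-----------
Sizes at the user interface are given as ``width x height`` (the common way
image resolutions are quoted); in-memory arrays are ``(rows=height,
cols=width)`` with the origin at the top-left.  Masks are stored on disk as
single-channel PNGs with values {0, 255} and held in memory as {0, 1}
(film = 1, background = 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "FieldImage",
    "BinaryMask",
    "DatasetSplit",
    "load_pair",
    "save_pair",
    "resize_pair",
    "split_dataset",
    "read_manifest",
    "load_manifest_pairs",
]


@dataclass
class FieldImage:
    """An RGB field photograph with acquisition metadata.

    ``pixels`` is an ``(H, W, 3)`` uint8 array.  ``weather`` is one of
    ``"sunny"``, ``"cloudy"`` or ``"unknown"``; ``height_m`` is the UAV
    flight height in metres (``None`` when unknown).
    """

    pixels: np.ndarray
    weather: str = "unknown"
    height_m: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.weather not in ("sunny", "cloudy", "unknown"):
            raise ValueError(f"unknown weather label: {self.weather!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Per-pixel film/background labels: an ``(H, W)`` array over {0, 1}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.labels.shape}")
        bad = np.setdiff1d(np.unique(self.labels), [0, 1])
        if bad.size:
            raise ValueError(f"mask values must be 0 or 1, found {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test partition of pair ids."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def __post_init__(self) -> None:
        all_ids = self.train + self.validation + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split lists must be disjoint")


def load_pair(image_path: str | Path, mask_path: str | Path) -> tuple[FieldImage, BinaryMask]:
    """Load an image/mask pair from PNG files.

    Mask files may use either {0, 255} or {0, 1} encoding; both are
    normalised to {0, 1}.  Any other pixel level is a format error.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = np.asarray(Image.open(image_path).convert("RGB"))
    raw = np.asarray(Image.open(mask_path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    levels = np.unique(raw)
    if np.isin(levels, [0, 255]).all():
        labels = (raw > 0).astype(np.uint8)
    elif np.isin(levels, [0, 1]).all():
        labels = raw.astype(np.uint8)
    else:
        bad = np.setdiff1d(levels, [0, 1, 255]).tolist()
        raise ValueError(f"mask {mask_path} is not binary: unexpected pixel values {bad}")
    if img.shape[:2] != labels.shape:
        raise ValueError(
            f"image/mask shape mismatch: {img.shape[:2]} vs {labels.shape} "
            f"({image_path}, {mask_path})"
        )
    return FieldImage(img, source_id=image_path.stem), BinaryMask(labels)


def save_pair(image: FieldImage, mask: BinaryMask, image_path: str | Path, mask_path: str | Path) -> None:
    """Write the pair as PNGs (mask scaled to {0, 255})."""
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    Image.fromarray(image.pixels).save(image_path)
    Image.fromarray(mask.labels * np.uint8(255)).save(mask_path)


def resize_pair(
    image: FieldImage,
    mask: BinaryMask,
    out_width: int = 1200,
    out_height: int = 600,
) -> tuple[FieldImage, BinaryMask]:
    """Resize a pair to ``out_width x out_height`` (default 1200 x 600).

    The image is resampled bilinearly, the mask nearest-neighbour so that
    labels stay in {0, 1}.
    """
    if out_width <= 0 or out_height <= 0:
        raise ValueError("output dimensions must be positive")
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if (out_height, out_width) == image.shape:
        return image, mask
    img = Image.fromarray(image.pixels).resize((out_width, out_height), Image.BILINEAR)
    msk = Image.fromarray(mask.labels).resize((out_width, out_height), Image.NEAREST)
    resized_img = FieldImage(
        np.asarray(img), weather=image.weather, height_m=image.height_m, source_id=image.source_id
    )
    return resized_img, BinaryMask(np.asarray(msk))


def split_dataset(
    ids: list,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministically partition ``ids`` into train/validation/test.

    Validation and test sizes are ``round(n * ratio)``; the remainder goes
    to train, so 600 ids with the default ratios split 480/60/60.
    """
    if not ids:
        raise ValueError("cannot split an empty id list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(ids)
    n_val = round(n * ratios[1])
    n_test = round(n * ratios[2])
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("ratios leave no room for a training set")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
    )


def load_manifest_pairs(
    data_dir: str | Path, splits: set[str] | None = None
) -> list[tuple[FieldImage, BinaryMask]]:
    """Load image/mask pairs listed in ``data_dir/manifest.csv``.

    Weather and height metadata from the manifest are attached to each
    image.  ``splits`` restricts rows to the given split labels.
    """
    data_dir = Path(data_dir)
    pairs = []
    for row in read_manifest(data_dir / "manifest.csv"):
        if splits is not None and row["split"] not in splits:
            continue
        img, msk = load_pair(
            data_dir / "images" / row["filename"], data_dir / "masks" / row["filename"]
        )
        img.weather = row["weather"]
        img.height_m = row["height_m"]
        pairs.append((img, msk))
    return pairs


def read_manifest(path: str | Path) -> list[dict]:
    """Read a dataset manifest CSV into a list of row dicts.

    Expected header: ``filename,split,weather,height_m,true_coverage_pct,seed``.
    """
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"manifest {path} is empty")
    for row in rows:
        row["height_m"] = float(row["height_m"])
        row["true_coverage_pct"] = float(row["true_coverage_pct"])
        row["seed"] = int(row["seed"])
    return rows
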