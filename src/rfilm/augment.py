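"""Stochastic training augmentation: crop, flips, brightness.

Exactly four operations are applied per sample, per epoch: a uniformly
positioned crop (default 1024 x 512 out of the 1200 x 600 working
resolution), independent left-right and up-down flips (p = 0.5 each), and
a multiplicative brightness factor drawn from U(0.8, 1.2) applied to the
image only.  Geometry is applied identically to image and mask, so the
mask alphabet {0, 1} and the image/mask pairing are preserved.  One
augmented variant of each training pair is produced per epoch: 480
originals over 55 epochs stream 26,400 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rfilm.dataio import BinaryMask, FieldImage

__all__ = ["AugmentConfig", "augment_pair", "EpochStream", "epoch_stream"]


@dataclass(frozen=True)
class AugmentConfig:
    crop_width: int = 1024
    crop_height: int = 512
    p_flip_lr: float = 0.5
    p_flip_ud: float = 0.5
    brightness_factor_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_width <= 0 or self.crop_height <= 0:
            raise ValueError("crop dimensions must be positive")
        if not (0 <= self.p_flip_lr <= 1 and 0 <= self.p_flip_ud <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        lo, hi = self.brightness_factor_range
        if lo <= 0 or lo > hi:
            raise ValueError("brightness range must be ordered and positive")


def augment_pair(
    image: FieldImage,
    mask: BinaryMask,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[FieldImage, BinaryMask]:
    """One random crop + flips + brightness adjustment of a pair."""
    h, w = image.shape
    ch, cw = cfg.crop_height, cfg.crop_width
    if h < ch or w < cw:
        raise ValueError(f"image {w}x{h} smaller than crop {cw}x{ch}")
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    img = image.pixels[top : top + ch, left : left + cw]
    msk = mask.labels[top : top + ch, left : left + cw]

    if rng.random() < cfg.p_flip_lr:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.p_flip_ud:
        img, msk = img[::-1], msk[::-1]

    factor = rng.uniform(*cfg.brightness_factor_range)
    img = np.clip(img.astype(np.float32) * factor, 0, 255).astype(np.uint8)

    out_img = FieldImage(
        img, weather=image.weather, height_m=image.height_m, source_id=image.source_id
    )
    return out_img, BinaryMask(np.ascontiguousarray(msk))


class EpochStream:
    """Iterator of augmented pairs with an audit counter.

    Yields one fresh augmentation of every training pair per epoch, for
    ``len(train_pairs) * epochs`` samples in total (exposed as
    ``expected_total``; ``count`` tracks samples actually yielded).
    """

    def __init__(
        self,
        train_pairs: list[tuple[FieldImage, BinaryMask]],
        cfg: AugmentConfig,
        epochs: int,
    ) -> None:
        if not train_pairs:
            raise ValueError("empty training list")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.train_pairs = train_pairs
        self.cfg = cfg
        self.epochs = epochs
        self.count = 0
        self.expected_total = len(train_pairs) * epochs
        self._rng = np.random.default_rng(cfg.seed)

    def __iter__(self):
        for epoch in range(self.epochs):
            order = self._rng.permutation(len(self.train_pairs))
            for i in order:
                image, mask = self.train_pairs[i]
                pair = augment_pair(image, mask, self.cfg, self._rng)
                self.count += 1
                yield epoch, pair

    def epoch_iter(self, epoch: int):
        """Samples of a single epoch (used by the training loop)."""
        order = self._rng.permutation(len(self.train_pairs))
        for i in order:
            image, mask = self.train_pairs[i]
            pair = augment_pair(image, mask, self.cfg, self._rng)
            self.count += 1
            yield pair


def epoch_stream(
    train_pairs: list[tuple[FieldImage, BinaryMask]],
    cfg: AugmentConfig,
    epochs: int,
) -> EpochStream:
    """Build the per-epoch augmentation stream (see :class:`EpochStream`)."""
    return EpochStream(train_pairs, cfg, epochs)
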