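"""Paired image/mask augmentation.

Geometric transforms (random crop-and-rescale, horizontal/vertical flips) are
applied identically to the image and its mask; photometric transforms
(brightness, saturation, contrast) touch the image only.  The mask is
resampled nearest-neighbour so it stays binary.  All ranges contain the
identity, so the identity transform is always reachable, and a fixed seed
makes the draw reproducible.

The augmentation factor is realized as sampling-with-replacement during
training rather than by materializing copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._interp import bilinear_resize
from ..errors import SizingError, ValidationError

__all__ = ["AugmentationConfig", "augment_pair"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentationConfig:
    brightness_delta: float = 0.30
    saturation_range: tuple[float, float] = (0.7, 1.3)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    hflip: bool = True
    vflip: bool = True
    crop_rescale_to: tuple[int, int] = (256, 256)
    crop_scale_range: tuple[float, float] = (0.7, 1.0)
    augmentation_factor: int = 2048

    def __post_init__(self):
        if self.brightness_delta < 0:
            raise ValidationError("brightness_delta must be >= 0")
        for name, (lo, hi) in (
            ("saturation_range", self.saturation_range),
            ("contrast_range", self.contrast_range),
            ("crop_scale_range", self.crop_scale_range),
        ):
            if not (0 < lo <= 1.0 <= hi):
                raise ValidationError(f"{name} must contain the identity value 1.0")
        if self.augmentation_factor < 1:
            raise ValidationError("augmentation_factor must be >= 1")


def _nearest_indices(n_in: int, n_out: int) -> np.ndarray:
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    return np.clip(np.floor(src + 0.5).astype(np.intp), 0, n_in - 1)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig = AugmentationConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One augmented (image, mask) pair.

    ``image`` is (H, W, 3) uint8 or [0, 1] float; ``mask`` is (H, W) boolean.
    Returns a float image in [0, 1] and a boolean mask, both of spatial size
    ``config.crop_rescale_to``.
    """
    image = np.asarray(image, dtype=float)
    if image.max() > 1.0:
        image = image / 255.0
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValidationError("image and mask must share spatial dimensions")
    h, w = mask.shape
    out_h, out_w = config.crop_rescale_to
    rng = np.random.default_rng(seed)

    scale = rng.uniform(*config.crop_scale_range)
    crop_h = max(int(round(scale * out_h)), 1)
    crop_w = max(int(round(scale * out_w)), 1)
    if crop_h > h or crop_w > w:
        raise SizingError(
            f"image {h}x{w} is smaller than the {crop_h}x{crop_w} crop the "
            "configured rescale range requires"
        )
    r0 = int(rng.integers(0, h - crop_h + 1))
    c0 = int(rng.integers(0, w - crop_w + 1))
    img = image[r0 : r0 + crop_h, c0 : c0 + crop_w]
    msk = mask[r0 : r0 + crop_h, c0 : c0 + crop_w]

    if (crop_h, crop_w) != (out_h, out_w):
        img = np.clip(
            bilinear_resize(img.transpose(2, 0, 1), (out_h, out_w)).transpose(1, 2, 0),
            0.0,
            1.0,
        )
        msk = msk[np.ix_(_nearest_indices(crop_h, out_h), _nearest_indices(crop_w, out_w))]

    if config.hflip and rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]

    delta = rng.uniform(-config.brightness_delta, config.brightness_delta)
    sat = rng.uniform(*config.saturation_range)
    con = rng.uniform(*config.contrast_range)
    img = img + delta
    gray = (img @ _LUMA)[..., None]
    img = gray + sat * (img - gray)
    img = img.mean() + con * (img - img.mean())
    return np.clip(img, 0.0, 1.0), msk.copy()
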