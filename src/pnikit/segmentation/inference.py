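"""Whole-image inference by overlapped tiling.

The image is covered with a clamped patch grid (stride = tile - overlap);
per-tile predictions are blended by averaging wherever tiles overlap, so any
model that is consistent across tile boundaries yields a seamless map.
Images smaller than one tile are padded reflectively, predicted, and cropped
back — not an error.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from ..io import ImageTile, make_patch_grid
from ..postprocess import ProbabilityMap

__all__ = ["predict_map"]


def predict_map(
    model,
    image: ImageTile | np.ndarray,
    tile: int = 256,
    overlap: int = 32,
    channel: str = "nerve",
    mpp: float | None = None,
    batch_size: int = 8,
) -> ProbabilityMap:
    """Run ``model`` (anything with a ``predict((N, H, W, 3)) -> (N, H, W)``
    method) over an RGB image and blend the tiles into one probability map."""
    if not (0 <= overlap < tile):
        raise ValidationError("overlap must satisfy 0 <= overlap < tile")
    if isinstance(image, ImageTile):
        pixels = image.pixels
        mpp = image.mpp if mpp is None else mpp
    else:
        pixels = np.asarray(image)
    if mpp is None:
        mpp = 0.23
    x = pixels.astype(float)
    if x.max() > 1.0:
        x = x / 255.0
    h, w = x.shape[:2]

    pad_h, pad_w = max(tile - h, 0), max(tile - w, 0)
    if pad_h or pad_w:
        x = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    hp, wp = x.shape[:2]

    grid = make_patch_grid(hp, wp, tile, tile - overlap)
    acc = np.zeros((hp, wp))
    weight = np.zeros((hp, wp))
    origins = list(grid.patches)
    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        batch = np.stack([x[r : r + tile, c : c + tile] for r, c in chunk])
        preds = np.asarray(model.predict(batch))
        for (r, c), p in zip(chunk, preds):
            acc[r : r + tile, c : c + tile] += p
            weight[r : r + tile, c : c + tile] += 1.0
    values = np.clip(acc / weight, 0.0, 1.0)[:h, :w]
    return ProbabilityMap(values, mpp=mpp, channel=channel)
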