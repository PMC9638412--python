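"""Reading and writing the formats the pipeline touches.

Images, masks and probability maps travel as TIFF or PNG; rectangle
annotations travel as JSON; diagnostic-time tables travel as CSV.  Coordinates
are 0-based, row-major, origin at the top-left, and bounding boxes are
half-open ``(row0, col0, row1, col1)`` — stated once here, used everywhere.

Probability maps are stored as 16-bit grayscale (``stored = round(p * 65535)``,
half up) so that downstream histogram thresholding sees negligible
quantization error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, SizingError, ValidationError

__all__ = [
    "ImageTile",
    "AnnotationRecord",
    "PatchGrid",
    "LABELS",
    "SOURCES",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_probability_map",
    "write_probability_map",
    "make_patch_grid",
    "read_annotations",
    "write_annotations",
    "read_timing_csv",
    "write_timing_csv",
]

LABELS = ("PNI", "normal_nerve")
SOURCES = ("algorithm", "human")

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageTile:
    """An RGB tile with its physical scale and position in the source image."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float = 0.23
    origin: tuple[int, int] = (0, 0)
    source_id: str = ""

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValidationError("mpp must be positive")
        if any(o < 0 for o in self.origin):
            raise ValidationError("origin components must be non-negative")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("pixels must be an (H, W, 3) array")


@dataclass(frozen=True)
class AnnotationRecord:
    """One labeled rectangle: a PNI or normal-nerve call from the algorithm or
    a human reader."""

    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    label: str
    source: str
    slide_id: str

    def __post_init__(self):
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValidationError(f"bbox must be non-empty and half-open: {self.bbox}")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class PatchGrid:
    """Origins of a sliding-window tiling of a source image."""

    patch_size: tuple[int, int]
    stride: tuple[int, int]
    patches: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if any(s > p for s, p in zip(self.stride, self.patch_size)):
            raise ValidationError("stride must be <= patch_size componentwise")


def read_image(path) -> np.ndarray:
    """Read an image file into a numpy array (shape and dtype as stored)."""
    try:
        return np.asarray(iio.imread(path))
    except (OSError, ValueError, RuntimeError) as exc:  # plugins differ in what they raise
        raise FormatError(f"could not read image {path}: {exc}") from exc


def write_image(pixels: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(pixels))


def read_mask(path, foreground_threshold: int = 128) -> np.ndarray:
    """Read a stored mask: pixels with value >= threshold become foreground.

    RGB inputs are converted by luminance first.  Returns a boolean array of
    the stored shape.
    """
    raw = read_image(path)
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[..., :3]
        if raw.shape[2] != 3:
            raise FormatError(f"unsupported channel count {raw.shape[2]} in {path}")
        raw = raw.astype(float) @ _LUMA
    elif raw.ndim != 2:
        raise FormatError(f"unsupported mask dimensionality {raw.ndim} in {path}")
    return np.asarray(raw) >= foreground_threshold


def write_mask(mask: np.ndarray, path) -> None:
    """Store a boolean mask as 8-bit 0/255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    write_image((mask.astype(bool) * np.uint8(255)), path)


def write_probability_map(values: np.ndarray, path) -> None:
    """Store a [0, 1] probability map as 16-bit grayscale.

    stored = round(p * 65535), rounding half up, so the per-pixel read-back
    error is at most 1/65535.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("probability map must be 2-D")
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValidationError("probability-map values must lie in [0, 1]")
    stored = np.floor(values * 65535.0 + 0.5).astype(np.uint16)
    iio.imwrite(path, stored)


def read_probability_map(path) -> np.ndarray:
    """Read a 16-bit probability map back to float values in [0, 1]."""
    raw = read_image(path)
    if raw.ndim != 2:
        raise FormatError(f"probability map must be single-channel: {path}")
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    raise FormatError(f"unsupported probability-map bit depth {raw.dtype} in {path}")


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    if patch > dim:
        raise SizingError(f"patch extent {patch} exceeds image extent {dim}")
    origins = list(range(0, dim - patch + 1, stride))
    if origins[-1] + patch < dim:
        origins.append(dim - patch)  # clamp: last patch ends at the edge
    return origins


def make_patch_grid(
    image_h: int,
    image_w: int,
    patch_size: int | tuple[int, int],
    stride: int | tuple[int, int] | None = None,
) -> PatchGrid:
    """Tile an image with patches at multiples of ``stride``.

    The final origin on each axis is clamped so the last patch ends exactly at
    the image edge: every pixel is covered, no patch runs out of bounds.
    """
    ph, pw = (patch_size, patch_size) if np.isscalar(patch_size) else patch_size
    if stride is None:
        stride = (ph, pw)
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    if sh < 1 or sw < 1:
        raise ValidationError("stride must be positive")
    rows = _axis_origins(image_h, ph, sh)
    cols = _axis_origins(image_w, pw, sw)
    return PatchGrid(
        patch_size=(ph, pw),
        stride=(sh, sw),
        patches=tuple((r, c) for r in rows for c in cols),
    )


_ANNOTATION_KEYS = {"bbox", "label", "source", "slide_id"}


def write_annotations(records: Sequence[AnnotationRecord], path) -> None:
    payload = [asdict(r) | {"bbox": list(r.bbox)} for r in records]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a JSON array of annotation records.  Unknown keys are rejected."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed annotation JSON in {path}: {exc}") from exc
    if not isinstance(payload, list):
        raise FormatError(f"annotation file must hold a JSON array: {path}")
    records = []
    for obj in payload:
        if not isinstance(obj, dict):
            raise FormatError("annotation entries must be JSON objects")
        extra = set(obj) - _ANNOTATION_KEYS
        if extra:
            raise FormatError(f"unknown annotation keys: {sorted(extra)}")
        missing = _ANNOTATION_KEYS - set(obj)
        if missing:
            raise FormatError(f"missing annotation keys: {sorted(missing)}")
        try:
            records.append(
                AnnotationRecord(
                    bbox=tuple(int(v) for v in obj["bbox"]),
                    label=obj["label"],
                    source=obj["source"],
                    slide_id=obj["slide_id"],
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise FormatError(f"invalid annotation record in {path}: {exc}") from exc
    return records


def read_timing_csv(path) -> pd.DataFrame:
    """Read a diagnostic-time table (columns slide_id, t_without_sec, t_with_sec)."""
    df = pd.read_csv(path)
    required = {"slide_id", "t_without_sec", "t_with_sec"}
    if not required.issubset(df.columns):
        raise FormatError(f"timing CSV must have columns {sorted(required)}")
    return df


def write_timing_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
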