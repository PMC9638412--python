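"""Size-filter calibration and pixel-area / cell-count conversions.

The rule flow removes small "irregular" components from the PNI probability
map before any nerve is inspected.  The removal cutoff is calibrated from an
observed sample of irregular-component areas: at significance level ``alpha``
the cutoff is the empirical upper (1 - alpha) quantile of the sample, taken
with the nearest-rank convention so the cutoff is always an observed area.
Combined with the filter's ``area <= cutoff`` removal rule this removes at
least a fraction (1 - alpha) of the calibration sample.

The companion conversions translate a pixel area into an equivalent number of
tumor cells, modelling cells as circles of a given mean diameter at a given
slide resolution.  At 0.23 um/px and a 13.5 um mean cell diameter, a
21,632 px^2 cutoff corresponds to a detection limit of ~8 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "PixelGeometry",
    "SizeFilterCalibration",
    "CellEquivalent",
    "calibrate_cutoff",
    "pixels_to_cells",
    "cells_to_pixels",
]


@dataclass(frozen=True)
class PixelGeometry:
    """Physical scale of a slide and the mean tumor-cell diameter.

    mpp
        Microns per pixel (0.23 for a 400x scan on the scanner modelled here).
    cell_diameter_um
        Mean diameter of a malignant squamous cell, in microns.
    """

    mpp: float = 0.23
    cell_diameter_um: float = 13.5

    def __post_init__(self):
        if not (self.mpp > 0 and self.cell_diameter_um > 0):
            raise ValidationError("mpp and cell diameter must be positive")

    @property
    def cell_area_px2(self) -> float:
        """Area of one circular cell, in pixels squared."""
        radius_px = (self.cell_diameter_um / 2.0) / self.mpp
        return math.pi * radius_px * radius_px


def calibrate_cutoff(sample_areas_px2: Sequence[float], alpha: float) -> float:
    """Nearest-rank upper quantile of a component-area sample.

    Sorts the areas ascending and returns the element at 1-based rank
    ``ceil((1 - alpha) * n)``.  The returned cutoff is always a member of the
    sample.  Permutation-invariant; monotone non-decreasing in (1 - alpha).
    """
    areas = np.asarray(sample_areas_px2, dtype=float)
    if areas.size == 0:
        raise ValidationError("calibration sample must be non-empty")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    # small epsilon so float representation of (1 - alpha) cannot bump an
    # exactly-integral rank upward
    rank = math.ceil((1.0 - alpha) * areas.size - 1e-9)  # 1-based
    rank = min(max(rank, 1), areas.size)
    return float(np.sort(areas)[rank - 1])


@dataclass(frozen=True)
class SizeFilterCalibration:
    """A calibrated size filter: the sample it came from, the significance
    level, and the resulting cutoff (always an observed sample area)."""

    sample_areas_px2: tuple
    alpha: float
    cutoff_px2: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "cutoff_px2", calibrate_cutoff(self.sample_areas_px2, self.alpha)
        )

    @classmethod
    def from_sample(cls, sample_areas_px2: Sequence[float], alpha: float) -> "SizeFilterCalibration":
        return cls(tuple(float(a) for a in sample_areas_px2), alpha)


@dataclass(frozen=True)
class CellEquivalent:
    """A pixel area expressed as a number of circular tumor cells."""

    cells: float
    rounded: int


def pixels_to_cells(area_px2: float, geom: PixelGeometry = PixelGeometry()) -> CellEquivalent:
    """Convert a pixel area to an equivalent tumor-cell count.

    cells = area_px2 * mpp^2 / (pi * (d/2)^2); the integer form uses
    round-half-up.
    """
    if area_px2 < 0:
        raise ValidationError("area must be non-negative")
    cells = (area_px2 * geom.mpp**2) / (
        math.pi * (geom.cell_diameter_um / 2.0) ** 2
    )
    return CellEquivalent(cells=cells, rounded=int(math.floor(cells + 0.5)))


def cells_to_pixels(n_cells: float, geom: PixelGeometry = PixelGeometry()) -> float:
    """Exact algebraic inverse of :func:`pixels_to_cells` (float cell count)."""
    if n_cells < 0:
        raise ValidationError("cell count must be non-negative")
    return n_cells * math.pi * (geom.cell_diameter_um / 2.0) ** 2 / geom.mpp**2
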