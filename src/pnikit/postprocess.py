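"""The domain-knowledge rule flow: from two probability maps to per-nerve
PNI/normal decisions.

The two segmentation stages emit a nerve map and a PNI map.  The nerve map is
smoothed with a Gaussian pyramid (reduce then expand), thresholded, and
cleaned with a morphological opening-then-closing ("smoothing construction")
that removes staircase right angles and isolated speckle.  The PNI map is
binarized with the stricter of a constant threshold and Otsu's threshold,
labeled into connected components, and passed through a size filter that
removes small irregular components (default cutoff 21,632 px^2, the calibrated
90th percentile of the irregular-component size distribution, roughly an
8-cell detection limit).  Finally each nerve structure is inspected: it is
called PNI-positive iff a retained PNI component comes within a Chebyshev
adjacency distance of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from ._interp import bilinear_resize
from .errors import ShapeError, SizingError, ValidationError

__all__ = [
    "ProbabilityMap",
    "Component",
    "NerveStructure",
    "DecisionConfig",
    "DecisionFlowResult",
    "OtsuResult",
    "pyramid_smooth",
    "otsu_threshold",
    "binarize_pni",
    "extract_nerve_mask",
    "extract_components",
    "size_filter",
    "assign_pni",
    "run_decision_flow",
]

# 5-tap binomial approximation of a Gaussian; sums to 1.
_PYRAMID_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class ProbabilityMap:
    """A single-channel segmentation output: values in [0, 1] plus pixel
    geometry and the channel it scores (nerve or pni)."""

    values: np.ndarray
    mpp: float = 0.23
    channel: str = "nerve"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.size == 0:
            raise ValidationError("probability map must be a non-empty 2-D grid")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise ValidationError("probability-map values must lie in [0, 1]")
        if self.mpp <= 0:
            raise ValidationError("mpp must be positive")
        if self.channel not in ("nerve", "pni"):
            raise ValidationError("channel must be 'nerve' or 'pni'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Component:
    """One connected region of a binary mask."""

    label: int
    area_px2: int
    bbox: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    centroid: tuple[float, float]
    pixels: np.ndarray  # (area, 2) int coordinates, row-major order
    mask_shape: tuple[int, int]


@dataclass
class NerveStructure:
    """One detected nerve region and its PNI/normal call.

    The call is structural: ``predicted_class == "PNI"`` iff
    ``supporting_pni_components`` is non-empty.
    """

    id: int
    region: Component
    supporting_pni_components: list[int] = field(default_factory=list)
    truth_class: str | None = None

    @property
    def predicted_class(self) -> str:
        return "PNI" if self.supporting_pni_components else "normal"


@dataclass(frozen=True)
class DecisionConfig:
    """Tunable parameters of the rule flow (defaults are the shipped
    operating point; the cutoff is the calibrated 90th-percentile value)."""

    pyramid_levels: int = 2
    nerve_threshold: float = 0.5
    smoothing_radius_px: int = 3
    pni_const_threshold: float = 0.5
    size_cutoff_px2: float = 21632
    adjacency_px: int = 5
    connectivity: int = 8

    def __post_init__(self):
        if not (0.0 < self.nerve_threshold < 1.0 and 0.0 < self.pni_const_threshold < 1.0):
            raise ValidationError("thresholds must lie in (0, 1)")
        if self.size_cutoff_px2 < 0:
            raise ValidationError("size cutoff must be >= 0")
        if self.adjacency_px < 0:
            raise ValidationError("adjacency must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.pyramid_levels < 0 or self.smoothing_radius_px < 0:
            raise ValidationError("pyramid levels and smoothing radius must be >= 0")


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


def _reduce_once(a: np.ndarray) -> np.ndarray:
    """One pyramid reduce: separable 5-tap binomial blur (reflect padding)
    followed by factor-2 decimation keeping even-indexed samples."""
    blurred = ndimage.correlate1d(a, _PYRAMID_KERNEL, axis=0, mode="reflect")
    blurred = ndimage.correlate1d(blurred, _PYRAMID_KERNEL, axis=1, mode="reflect")
    return blurred[::2, ::2]


def pyramid_smooth(pmap: ProbabilityMap, levels: int) -> ProbabilityMap:
    """Gaussian-pyramid smoothing: ``levels`` reduce steps then bilinear
    expansion back through the same shapes to the original dimensions."""
    if levels < 0:
        raise ValidationError("levels must be >= 0")
    a = pmap.values
    if min(a.shape) < 2**levels:
        raise SizingError(
            f"map of shape {a.shape} is too small for {levels} pyramid levels"
        )
    shapes = []
    for _ in range(levels):
        shapes.append(a.shape)
        a = _reduce_once(a)
    for shape in reversed(shapes):
        a = bilinear_resize(a, shape)
    a = np.clip(a, 0.0, 1.0)
    return replace(pmap, values=a)


def otsu_threshold(pmap: ProbabilityMap | np.ndarray, bins: int = 256) -> OtsuResult:
    """Otsu's threshold on a fixed [0, 1] histogram.

    The histogram has ``bins`` equal-width bins over [0, 1] (values equal to
    1 fall in the last bin).  Candidate thresholds are bin upper edges; the
    returned threshold maximizes the between-class variance
    w0 * w1 * (mu0 - mu1)^2, with ties broken toward the smallest edge.  If
    only a single bin is occupied the split is undefined and the result is
    flagged degenerate, carrying that bin's upper edge.
    """
    values = pmap.values if isinstance(pmap, ProbabilityMap) else np.asarray(pmap, float)
    if values.size == 0:
        raise ValidationError("cannot threshold an empty map")
    idx = np.clip(np.floor(values * bins).astype(np.intp), 0, bins - 1)
    hist = np.bincount(idx.ravel(), minlength=bins).astype(float)
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        return OtsuResult(threshold=float((occupied[0] + 1) / bins), degenerate=True)

    centers = (np.arange(bins) + 0.5) / bins
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1] / total  # class 0 = bins 0..k, k = 0..bins-2
    w1 = 1.0 - w0
    csum = np.cumsum(hist * centers)
    mu0 = np.divide(csum[:-1], np.cumsum(hist)[:-1], out=np.zeros(bins - 1), where=np.cumsum(hist)[:-1] > 0)
    mu1 = np.divide(csum[-1] - csum[:-1], (total - np.cumsum(hist)[:-1]),
                    out=np.zeros(bins - 1), where=(total - np.cumsum(hist)[:-1]) > 0)
    variance = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(variance))  # argmax returns the first (smallest) maximizer
    return OtsuResult(threshold=float((k + 1) / bins), degenerate=False)


def binarize_pni(
    pmap: ProbabilityMap, const_threshold: float = 0.5, bins: int = 256
) -> np.ndarray:
    """Binarize the PNI map with the stricter of the constant and Otsu
    thresholds (Otsu alone can fall below what a reader would call signal; the
    constant floor keeps faint diffuse responses out).

    Degenerate Otsu (single occupied bin) falls back to the constant
    threshold alone.  Foreground is strictly greater than the effective
    threshold.
    """
    if not (0.0 < const_threshold < 1.0):
        raise ValidationError("const_threshold must lie in (0, 1)")
    otsu = otsu_threshold(pmap, bins=bins)
    effective = const_threshold if otsu.degenerate else max(const_threshold, otsu.threshold)
    return pmap.values > effective


def extract_nerve_mask(pmap: ProbabilityMap, cfg: DecisionConfig) -> np.ndarray:
    """Nerve mask: pyramid smoothing, thresholding, then a morphological
    opening-then-closing with a disk.  The opening removes protrusions and
    staircase right-angle artifacts; the closing fills notches."""
    smoothed = pyramid_smooth(pmap, cfg.pyramid_levels)
    mask = smoothed.values > cfg.nerve_threshold
    if cfg.smoothing_radius_px > 0:
        footprint = disk(cfg.smoothing_radius_px)
        mask = ndimage.binary_opening(mask, structure=footprint)
        mask = ndimage.binary_closing(mask, structure=footprint)
    return mask


def extract_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Connected-component labeling with labels ordered by first-encountered
    pixel in a row-major scan."""
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3), bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    flat = labeled.ravel()
    fg_labels = flat[flat > 0]
    # re-map labels into row-major first-encounter order
    labs, first_idx = np.unique(fg_labels, return_index=True)
    ordered = labs[np.argsort(first_idx)]
    remap = np.zeros(n + 1, dtype=np.intp)
    remap[ordered] = np.arange(1, ordered.size + 1)
    labeled = remap[labeled]

    components = []
    slices = ndimage.find_objects(labeled)
    for new_label, slc in enumerate(slices, start=1):
        local = labeled[slc] == new_label
        coords = np.argwhere(local)
        coords[:, 0] += slc[0].start
        coords[:, 1] += slc[1].start
        components.append(
            Component(
                label=new_label,
                area_px2=int(coords.shape[0]),
                bbox=(slc[0].start, slc[1].start, slc[0].stop, slc[1].stop),
                centroid=tuple(coords.mean(axis=0)),
                pixels=coords,
                mask_shape=mask.shape,
            )
        )
    return components


def size_filter(
    components: Iterable[Component], cutoff_px2: float
) -> tuple[list[Component], list[Component]]:
    """Partition components into (retained, removed) by ``area <= cutoff``.

    The <= rule pairs with the nearest-rank calibration: a cutoff equal to the
    empirical (1 - alpha) quantile removes at least that fraction of the
    calibration sample.
    """
    if cutoff_px2 < 0:
        raise ValidationError("cutoff must be >= 0")
    retained, removed = [], []
    for comp in components:
        (removed if comp.area_px2 <= cutoff_px2 else retained).append(comp)
    return retained, removed


def _chebyshev_dilate(comp: Component, radius: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Local mask of all pixels within Chebyshev distance ``radius`` of the
    component, together with its (row, col) offset in the full frame."""
    r0, c0, r1, c1 = comp.bbox
    h, w = comp.mask_shape
    rr0, cc0 = max(r0 - radius, 0), max(c0 - radius, 0)
    rr1, cc1 = min(r1 + radius, h), min(c1 + radius, w)
    local = np.zeros((rr1 - rr0, cc1 - cc0), bool)
    local[comp.pixels[:, 0] - rr0, comp.pixels[:, 1] - cc0] = True
    if radius > 0:
        # square footprint = Chebyshev ball
        local = ndimage.binary_dilation(local, np.ones((2 * radius + 1,) * 2, bool))
    return local, (rr0, cc0)


def assign_pni(
    nerves: Sequence[Component],
    pni_components: Sequence[Component],
    adjacency_px: int = 5,
) -> list[NerveStructure]:
    """Inspect each nerve for PNI: a nerve is positive iff some retained PNI
    component has a pixel within Chebyshev distance ``adjacency_px`` of the
    nerve (0 requires overlap).  One PNI component may support several
    nerves."""
    shapes = {c.mask_shape for c in list(nerves) + list(pni_components)}
    if len(shapes) > 1:
        raise ShapeError(f"component lists come from masks of differing shapes: {shapes}")
    structures = [NerveStructure(id=n.label, region=n) for n in nerves]
    if not nerves or not pni_components:
        return structures
    shape = nerves[0].mask_shape
    nerve_labels = np.zeros(shape, dtype=np.intp)
    for n in nerves:
        nerve_labels[n.pixels[:, 0], n.pixels[:, 1]] = n.label
    by_id = {s.id: s for s in structures}
    for comp in pni_components:
        local, (r_off, c_off) = _chebyshev_dilate(comp, adjacency_px)
        window = nerve_labels[r_off : r_off + local.shape[0], c_off : c_off + local.shape[1]]
        touched = np.unique(window[local])
        for lab in touched[touched > 0]:
            by_id[int(lab)].supporting_pni_components.append(comp.label)
    return structures


@dataclass
class DecisionFlowResult:
    """Per-nerve decisions plus the intermediate artifacts for audit."""

    nerves: list[NerveStructure]
    nerve_mask: np.ndarray
    pni_mask: np.ndarray
    nerve_components: list[Component]
    pni_components: list[Component]
    pni_retained: list[Component]
    pni_removed: list[Component]
    otsu: OtsuResult
    config: DecisionConfig


def run_decision_flow(
    nerve_map: ProbabilityMap,
    pni_map: ProbabilityMap,
    cfg: DecisionConfig = DecisionConfig(),
) -> DecisionFlowResult:
    """The full rule flow, in the order: nerve mask extraction and labeling;
    PNI binarization, labeling and size filtering; then per-nerve
    inspection.  Deterministic for identical inputs and config."""
    if nerve_map.shape != pni_map.shape:
        raise ShapeError(f"map shapes differ: {nerve_map.shape} vs {pni_map.shape}")
    if abs(nerve_map.mpp - pni_map.mpp) > 1e-12:
        raise ValidationError("maps must share mpp")
    nerve_mask = extract_nerve_mask(nerve_map, cfg)
    nerve_components = extract_components(nerve_mask, cfg.connectivity)
    otsu = otsu_threshold(pni_map)
    pni_mask = binarize_pni(pni_map, cfg.pni_const_threshold)
    pni_components = extract_components(pni_mask, cfg.connectivity)
    retained, removed = size_filter(pni_components, cfg.size_cutoff_px2)
    nerves = assign_pni(nerve_components, retained, cfg.adjacency_px)
    return DecisionFlowResult(
        nerves=nerves,
        nerve_mask=nerve_mask,
        pni_mask=pni_mask,
        nerve_components=nerve_components,
        pni_components=pni_components,
        pni_retained=retained,
        pni_removed=removed,
        otsu=otsu,
        config=cfg,
    )
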