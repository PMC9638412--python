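"""Reproducible synthetic histology-like scenes with ground truth.

A scene emulates an H&E-stained region at a configurable microns-per-pixel
scale: elliptical nerve fascicles wrapped in a darker perineurium ring, tumor
"cells" rendered as disks of the mean malignant-cell diameter that cluster
into nests hugging the perineurium of the nerves planted as PNI-positive, and
two kinds of spurious signal for the size filter to work on:

* free noise blobs, placed well clear of every nerve, with pixel areas drawn
  from a configurable distribution (default log-normal, chosen so most blobs
  fall below a ~21,632 px^2 cutoff while a tail exceeds it);
* small peri-nerve "speckles", placed 2-4 px outside the perineurium — close
  enough to trigger the PNI adjacency rule if they survive size filtering,
  emulating the spurious near-nerve responses a pixel-wise segmenter
  produces.

Everything is drawn from one seeded generator in a fixed order
(nerves -> nests -> speckles -> noise -> texture), so scenes are bit-identical
for a fixed spec and nerve placement does not depend on how much noise is
requested.  Structures are placed by rejection sampling with a bounded retry
budget; exhausting it raises instead of silently overlapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import PlacementError, SizingError, ValidationError
from .postprocess import ProbabilityMap

__all__ = [
    "NoiseSizeDist",
    "SceneSpec",
    "NerveRecord",
    "SyntheticScene",
    "generate_scene",
    "scene_to_probability_maps",
]

# rendering palette (RGB), loosely H&E: eosin-pink background, pale nerve
# fascicles, darker perineurium, hematoxylin-purple tumor cells
_BACKGROUND = np.array([235.0, 210.0, 218.0])
_NERVE_INTERIOR = np.array([208.0, 172.0, 188.0])
_PERINEURIUM = np.array([148.0, 108.0, 138.0])
_TUMOR_CELL = np.array([118.0, 72.0, 138.0])
_NOISE_BLOB = np.array([165.0, 118.0, 155.0])

_SPECKLE_GAP_PX = (2.0, 4.0)  # distance band outside the perineurium
_FOREGROUND_GAP_PX = 8  # minimum gap between separate planted structures


@dataclass(frozen=True)
class NoiseSizeDist:
    """Named distribution for noise-blob pixel areas.

    ``lognormal`` takes ``mean`` and ``sigma`` of the underlying normal;
    ``uniform`` takes ``low`` and ``high``.  Draws are rounded to integer
    areas and clipped below at 16 px^2 so every blob is renderable.
    """

    name: str = "lognormal"
    params: tuple[tuple[str, float], ...] = (("mean", 9.0), ("sigma", 0.8))

    def __post_init__(self):
        if self.name not in ("lognormal", "uniform"):
            raise ValidationError(f"unknown noise size distribution {self.name!r}")
        object.__setattr__(self, "params", tuple(self.params))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = dict(self.params)
        if self.name == "lognormal":
            draws = rng.lognormal(mean=p["mean"], sigma=p["sigma"], size=n)
        else:
            draws = rng.uniform(p["low"], p["high"], size=n)
        return np.maximum(np.floor(draws + 0.5).astype(int), 16)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Geometry is in pixels at ``mpp`` microns per pixel.  The defaults describe
    a 1280 x 1280 region at 0.23 um/px holding four nerves (semi-axes
    40-70 px, 6 px perineurium), half of them with planted PNI nests of 12-18
    tumor cells (cell diameter 13.5 um / 0.23 um/px ~ 58.7 px, packed at 0.85
    cell diameters so a nest is one connected mass well above the default
    size-filter cutoff), plus log-normally sized free noise blobs and three
    small peri-nerve speckles.
    """

    height_px: int = 1280
    width_px: int = 1280
    mpp: float = 0.23
    n_nerves: int = 4
    pni_fraction: float = 0.5
    nerve_axis_range_px: tuple[float, float] = (40.0, 70.0)
    perineurium_thickness_px: int = 6
    tumor_cell_diameter_px: float = 13.5 / 0.23
    pni_nest_cells: tuple[int, int] = (12, 18)
    nest_packing_frac: float = 0.85
    n_noise_blobs: int = 15
    noise_size_dist: NoiseSizeDist = field(default_factory=NoiseSizeDist)
    n_perinerve_speckles: int = 3
    speckle_area_range_px2: tuple[float, float] = (500.0, 8000.0)
    noise_clearance_px: float = 25.0
    background_texture: float = 0.02
    seed: int = 0
    max_place_attempts: int = 1000

    def __post_init__(self):
        if self.height_px < 1 or self.width_px < 1:
            raise ValidationError("canvas dimensions must be positive")
        if self.mpp <= 0:
            raise ValidationError("mpp must be positive")
        if not (0.0 <= self.pni_fraction <= 1.0):
            raise ValidationError("pni_fraction must lie in [0, 1]")
        lo, hi = self.nerve_axis_range_px
        if not (0 < lo <= hi):
            raise ValidationError("nerve axis range must be positive with min <= max")
        nlo, nhi = self.pni_nest_cells
        if not (0 < nlo <= nhi):
            raise ValidationError("pni_nest_cells must be positive with min <= max")
        if min(self.n_nerves, self.n_noise_blobs, self.n_perinerve_speckles) < 0:
            raise ValidationError("counts must be non-negative")
        if self.tumor_cell_diameter_px <= 0 or self.perineurium_thickness_px < 0:
            raise ValidationError("cell diameter must be positive, ring thickness >= 0")
        if not (0.0 < self.nest_packing_frac <= 2.0):
            raise ValidationError("nest_packing_frac must lie in (0, 2]")
        if self.max_place_attempts < 1:
            raise ValidationError("max_place_attempts must be >= 1")

    @property
    def n_pni_nerves(self) -> int:
        return int(math.floor(self.pni_fraction * self.n_nerves + 0.5))


@dataclass(frozen=True)
class NerveRecord:
    """Ground truth for one planted nerve: id, tight half-open bbox over the
    nerve region (perineurium included), and true class."""

    id: int
    bbox: tuple[int, int, int, int]
    truth_class: str  # "PNI" or "normal"


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    nerve_truth: np.ndarray  # bool
    pni_truth: np.ndarray  # bool, tumor pixels of planted nests
    noise_truth: np.ndarray  # bool, blobs + speckles
    nerve_labels: np.ndarray  # int, 0 background, record id per nerve pixel
    nerve_records: list[NerveRecord]
    spec: SceneSpec
    noise_areas_px2: tuple[int, ...] = ()  # the drawn free-blob areas, in draw order


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_coords(center, a, b, theta, shape):
    """Integer pixel coordinates inside a rotated ellipse, clipped to canvas."""
    cy, cx = center
    ext = max(a, b) + 1.0
    r0, r1 = int(math.floor(cy - ext)), int(math.ceil(cy + ext)) + 1
    c0, c1 = int(math.floor(cx - ext)), int(math.ceil(cx + ext)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.stack([yy[inside], xx[inside]], axis=1)


def _ellipse_radius(a, b, theta, phi):
    """Radius of a rotated ellipse along absolute direction ``phi``."""
    d = phi - theta
    return 1.0 / math.sqrt((math.cos(d) / a) ** 2 + (math.sin(d) / b) ** 2)


def _exact_area_blob(area, half_axes, theta, center, shape):
    """The ``area`` pixels with smallest elliptical norm around ``center``:
    an exactly-``area``-pixel blob.  Returns None if it would leave the
    canvas."""
    a, b = half_axes
    cy, cx = center
    ext = int(math.ceil(max(a, b))) + 3
    r0, r1 = int(round(cy)) - ext, int(round(cy)) + ext + 1
    c0, c1 = int(round(cx)) - ext, int(round(cx)) + ext + 1
    if r0 < 1 or c0 < 1 or r1 > shape[0] - 1 or c1 > shape[1] - 1:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = (u / a) ** 2 + (v / b) ** 2
    order = np.argsort(rho.ravel(), kind="stable")[:area]
    return np.stack([yy.ravel()[order], xx.ravel()[order]], axis=1)


def _sunflower_offsets(n, spacing):
    """Vogel-spiral offsets giving a compact round cluster with roughly
    ``spacing`` between neighbouring points."""
    k = np.arange(n, dtype=float)
    c = spacing * math.sqrt(math.sqrt(3.0) / (2.0 * math.pi))
    radius = c * np.sqrt(k)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    ang = k * golden
    return np.stack([radius * np.sin(ang), radius * np.cos(ang)], axis=1)


def _disk_offsets(radius: float) -> np.ndarray:
    ext = int(math.ceil(radius))
    yy, xx = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    inside = yy**2 + xx**2 <= radius**2
    return np.stack([yy[inside], xx[inside]], axis=1)


def _paint(mask: np.ndarray, coords: np.ndarray) -> None:
    mask[coords[:, 0], coords[:, 1]] = True


def _nest_extent(spec: SceneSpec) -> float:
    """Upper bound on the radius of a planted nest around its anchor."""
    if spec.n_pni_nerves == 0:
        return 0.0
    spacing = spec.nest_packing_frac * spec.tumor_cell_diameter_px
    c = spacing * math.sqrt(math.sqrt(3.0) / (2.0 * math.pi))
    return c * math.sqrt(spec.pni_nest_cells[1]) + spec.tumor_cell_diameter_px / 2.0 + 3.0


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene.  Deterministic for a fixed spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)
    ring = spec.perineurium_thickness_px
    nest_ext = _nest_extent(spec)

    lo, hi = spec.nerve_axis_range_px
    max_reff = hi + ring
    margin = max_reff + nest_ext + 4.0
    if spec.n_nerves > 0 and 2.0 * margin >= min(h, w):
        raise SizingError(
            f"canvas {h}x{w} cannot hold nerves of effective radius {margin:.0f}"
        )

    # --- nerves ------------------------------------------------------------
    nerve_labels = np.zeros(shape, dtype=np.intp)
    nerve_truth = np.zeros(shape, dtype=bool)
    geoms = []  # (cy, cx, a, b, theta)
    placed = False
    for _restart in range(20):
        geoms.clear()
        failed = False
        for _i in range(spec.n_nerves):
            for _attempt in range(spec.max_place_attempts):
                a = rng.uniform(lo, hi)
                b = rng.uniform(lo, a)
                theta = rng.uniform(0.0, math.pi)
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                reff = a + ring
                ok = all(
                    math.hypot(cy - gy, cx - gx)
                    >= reff + (ga + ring) + nest_ext + 2.0 * _FOREGROUND_GAP_PX
                    for gy, gx, ga, _gb, _gt in geoms
                )
                if ok:
                    geoms.append((cy, cx, a, b, theta))
                    break
            else:
                failed = True
                break
        if not failed:
            placed = True
            break
    if spec.n_nerves > 0 and not placed:
        raise PlacementError(
            "could not place non-overlapping nerves within the retry budget"
        )

    records: list[NerveRecord] = []
    interiors = []
    for i, (cy, cx, a, b, theta) in enumerate(geoms):
        outer = _ellipse_coords((cy, cx), a + ring, b + ring, theta, shape)
        inner = _ellipse_coords((cy, cx), a, b, theta, shape)
        _paint(nerve_truth, outer)
        nerve_labels[outer[:, 0], outer[:, 1]] = i + 1
        interiors.append(inner)
        bbox = (
            int(outer[:, 0].min()),
            int(outer[:, 1].min()),
            int(outer[:, 0].max()) + 1,
            int(outer[:, 1].max()) + 1,
        )
        records.append(NerveRecord(id=i + 1, bbox=bbox, truth_class="normal"))

    # --- PNI nests ---------------------------------------------------------
    pni_truth = np.zeros(shape, dtype=bool)
    k = spec.n_pni_nerves
    pni_ids = set()
    if k > 0:
        chosen = rng.choice(spec.n_nerves, size=k, replace=False)
        cell_r = spec.tumor_cell_diameter_px / 2.0
        disk_off = _disk_offsets(cell_r)
        spacing = spec.nest_packing_frac * spec.tumor_cell_diameter_px
        for i in sorted(int(c) for c in chosen):
            cy, cx, a, b, theta = geoms[i]
            # plant the nest pointing away from the nearest other nerve
            others = [g for j, g in enumerate(geoms) if j != i]
            if others:
                gy, gx, *_ = min(others, key=lambda g: math.hypot(g[0] - cy, g[1] - cx))
                phi_base = math.atan2(cy - gy, cx - gx)
            else:
                phi_base = rng.uniform(0.0, 2.0 * math.pi)
            planted = False
            for _attempt in range(spec.max_place_attempts):
                phi = phi_base + rng.uniform(-0.7, 0.7)
                n_cells = int(rng.integers(spec.pni_nest_cells[0], spec.pni_nest_cells[1] + 1))
                rot = rng.uniform(0.0, 2.0 * math.pi)
                jitter = rng.normal(0.0, 0.05 * spec.tumor_cell_diameter_px, size=(n_cells, 2))
                r_edge = _ellipse_radius(a + ring, b + ring, theta, phi)
                anchor = (cy + r_edge * math.sin(phi), cx + r_edge * math.cos(phi))
                offs = _sunflower_offsets(n_cells, spacing)
                cs, sn = math.cos(rot), math.sin(rot)
                offs = offs @ np.array([[cs, sn], [-sn, cs]]) + jitter
                centers = offs + np.array(anchor)
                if (
                    centers[:, 0].min() < cell_r + 1
                    or centers[:, 1].min() < cell_r + 1
                    or centers[:, 0].max() > h - cell_r - 2
                    or centers[:, 1].max() > w - cell_r - 2
                ):
                    continue
                nest = np.zeros(shape, dtype=bool)
                for cyx in centers:
                    coords = disk_off + np.floor(cyx + 0.5).astype(int)
                    _paint(nest, coords)
                # must touch its own nerve and stay clear of every other one
                touched = np.unique(nerve_labels[nest])
                touched = set(int(t) for t in touched if t > 0)
                if touched != {i + 1}:
                    continue
                grown = ndimage.binary_dilation(
                    nest, np.ones((2 * _FOREGROUND_GAP_PX + 1,) * 2, bool)
                )
                near = np.unique(nerve_labels[grown])
                if any(int(t) not in (0, i + 1) for t in near):
                    continue
                if (grown & pni_truth).any():
                    continue
                pni_truth |= nest
                pni_ids.add(i + 1)
                planted = True
                break
            if not planted:
                raise PlacementError(f"could not plant a PNI nest on nerve {i + 1}")
        records = [
            replace(r, truth_class="PNI") if r.id in pni_ids else r for r in records
        ]

    # --- spurious signal ----------------------------------------------------
    noise_truth = np.zeros(shape, dtype=bool)
    # distance from any nerve pixel, for clearance checks
    if spec.n_nerves > 0:
        nerve_dist = ndimage.distance_transform_edt(~nerve_truth)
    else:
        nerve_dist = np.full(shape, np.inf)
    forbidden = (
        ndimage.distance_transform_edt(~pni_truth) <= _FOREGROUND_GAP_PX
        if pni_truth.any()
        else np.zeros(shape, dtype=bool)
    )

    def _reserve(coords: np.ndarray) -> None:
        r0 = max(int(coords[:, 0].min()) - _FOREGROUND_GAP_PX - 1, 0)
        c0 = max(int(coords[:, 1].min()) - _FOREGROUND_GAP_PX - 1, 0)
        r1 = min(int(coords[:, 0].max()) + _FOREGROUND_GAP_PX + 2, h)
        c1 = min(int(coords[:, 1].max()) + _FOREGROUND_GAP_PX + 2, w)
        local = np.zeros((r1 - r0, c1 - c0), bool)
        local[coords[:, 0] - r0, coords[:, 1] - c0] = True
        grown = ndimage.distance_transform_edt(~local) <= _FOREGROUND_GAP_PX
        forbidden[r0:r1, c0:c1] |= grown

    # peri-nerve speckles: small, sub-cutoff, just outside the perineurium;
    # assigned round-robin over the shuffled normal nerves (that is where
    # near-nerve clutter matters — on a PNI nerve the planted nest masks it
    # and can wall off the whole perineurium), falling back to every nerve
    # when none is normal
    normal_idx = [i for i in range(spec.n_nerves) if (i + 1) not in pni_ids]
    pool = normal_idx if normal_idx else list(range(spec.n_nerves))
    speckle_targets = rng.permutation(pool) if pool else np.array([], int)
    for s in range(spec.n_perinerve_speckles if spec.n_nerves else 0):
        target = int(speckle_targets[s % len(pool)])
        cy, cx, a, b, theta = geoms[target]
        placed_speckle = False
        for _attempt in range(spec.max_place_attempts):
            area = int(rng.uniform(*spec.speckle_area_range_px2))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            gap = rng.uniform(*_SPECKLE_GAP_PX)
            aspect = rng.uniform(0.5, 1.0)
            b_half = math.sqrt(area * aspect / math.pi)
            a_half = b_half / aspect
            r_edge = _ellipse_radius(a + ring, b + ring, theta, phi)
            dist = r_edge + gap + b_half
            center = (cy + dist * math.sin(phi), cx + dist * math.cos(phi))
            coords = _exact_area_blob(area, (a_half, b_half), phi + math.pi / 2.0, center, shape)
            if coords is None:
                continue
            d = nerve_dist[coords[:, 0], coords[:, 1]]
            if d.min() < 2.0 or d.min() > 4.4:  # outside 1-px dilation, inside adjacency
                continue
            if forbidden[coords[:, 0], coords[:, 1]].any():
                continue
            if nerve_truth[coords[:, 0], coords[:, 1]].any():
                continue
            _paint(noise_truth, coords)
            _reserve(coords)
            placed_speckle = True
            break
        if not placed_speckle:
            raise PlacementError(f"could not place a peri-nerve speckle near nerve {target + 1}")

    # free noise blobs, clear of all nerves
    areas = spec.noise_size_dist.sample(rng, spec.n_noise_blobs)
    for area in areas:
        placed_blob = False
        for _attempt in range(spec.max_place_attempts):
            aspect = rng.uniform(0.45, 1.0)
            angle = rng.uniform(0.0, math.pi)
            b_half = math.sqrt(area * aspect / math.pi)
            a_half = b_half / aspect
            cy = rng.uniform(a_half + 2, h - a_half - 2)
            cx = rng.uniform(a_half + 2, w - a_half - 2)
            coords = _exact_area_blob(int(area), (a_half, b_half), angle, (cy, cx), shape)
            if coords is None:
                continue
            if nerve_dist[coords[:, 0], coords[:, 1]].min() < spec.noise_clearance_px:
                continue
            if forbidden[coords[:, 0], coords[:, 1]].any():
                continue
            _paint(noise_truth, coords)
            _reserve(coords)
            placed_blob = True
            break
        if not placed_blob:
            raise PlacementError(
                f"could not place a noise blob of {int(area)} px^2 within the retry budget"
            )

    # --- render -------------------------------------------------------------
    image = np.empty((h, w, 3), dtype=float)
    image[:] = _BACKGROUND
    image[nerve_truth] = _PERINEURIUM
    for inner in interiors:
        image[inner[:, 0], inner[:, 1]] = _NERVE_INTERIOR
    image[noise_truth] = _NOISE_BLOB
    image[pni_truth] = _TUMOR_CELL
    if spec.background_texture > 0:
        image += rng.normal(0.0, spec.background_texture * 255.0, size=image.shape)
    image = np.clip(image, 0.0, 255.0).astype(np.uint8)

    return SyntheticScene(
        image=image,
        nerve_truth=nerve_truth,
        pni_truth=pni_truth,
        noise_truth=noise_truth,
        nerve_labels=nerve_labels,
        nerve_records=records,
        spec=spec,
        noise_areas_px2=tuple(int(a) for a in areas),
    )


def scene_to_probability_maps(
    scene: SyntheticScene,
    blur_sigma: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ProbabilityMap, ProbabilityMap]:
    """Simulate the two segmentation outputs for a scene.

    The nerve map is the nerve truth mask softened by a Gaussian blur and
    corrupted by clipped additive noise; the PNI map is built the same way
    from the union of the planted-nest truth and the noise blobs — the
    spurious signal is deliberately part of the PNI foreground so the size
    filter has work to do.  With ``blur_sigma=0`` and ``noise_sd=0`` the maps
    equal the binary truth exactly.
    """
    if blur_sigma < 0:
        raise ValidationError("blur_sigma must be >= 0")
    if not (0.0 <= noise_sd < 0.5):
        raise ValidationError("noise_sd must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    def _one(mask: np.ndarray, channel: str) -> ProbabilityMap:
        v = mask.astype(float)
        if blur_sigma > 0:
            v = ndimage.gaussian_filter(v, blur_sigma)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        return ProbabilityMap(np.clip(v, 0.0, 1.0), mpp=scene.spec.mpp, channel=channel)

    nerve_pm = _one(scene.nerve_truth, "nerve")
    pni_pm = _one(scene.pni_truth | scene.noise_truth, "pni")
    return nerve_pm, pni_pm
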