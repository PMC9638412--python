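"""Rule-flow primitives checked against brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from pnikit.errors import ShapeError, SizingError, ValidationError
from pnikit.evaluation import truth_from_scene
from pnikit.postprocess import (
    Component,
    DecisionConfig,
    ProbabilityMap,
    assign_pni,
    binarize_pni,
    extract_components,
    extract_nerve_mask,
    otsu_threshold,
    pyramid_smooth,
    run_decision_flow,
    size_filter,
)
from pnikit.synthetic import NoiseSizeDist, SceneSpec, generate_scene, scene_to_probability_maps

from conftest import small_scene_spec

KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


# ---------------------------------------------------------------------------
# oracles (independent, loop-based implementations)


def reduce_oracle(a: np.ndarray) -> np.ndarray:
    """5-tap binomial blur with symmetric edge handling, then x2 decimation,
    computed with explicit loops."""
    h, w = a.shape
    pad = np.pad(a, 2, mode="symmetric")
    blurred = np.zeros_like(a, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for u in range(5):
                for v in range(5):
                    acc += KERNEL[u] * KERNEL[v] * pad[i + u, j + v]
            blurred[i, j] = acc
    return blurred[::2, ::2]


def expand_oracle(a: np.ndarray, out_shape) -> np.ndarray:
    """Half-pixel-convention bilinear upsampling with explicit loops."""
    hi, wi = a.shape
    ho, wo = out_shape
    out = np.zeros(out_shape)
    for i in range(ho):
        for j in range(wo):
            sy = min(max((i + 0.5) * hi / ho - 0.5, 0.0), hi - 1.0)
            sx = min(max((j + 0.5) * wi / wo - 0.5, 0.0), wi - 1.0)
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            y1, x1 = min(y0 + 1, hi - 1), min(x0 + 1, wi - 1)
            fy, fx = sy - y0, sx - x0
            out[i, j] = (
                a[y0, x0] * (1 - fy) * (1 - fx)
                + a[y0, x1] * (1 - fy) * fx
                + a[y1, x0] * fy * (1 - fx)
                + a[y1, x1] * fy * fx
            )
    return out


def otsu_oracle(values: np.ndarray, bins: int = 256):
    """Exhaustive between-class-variance search over all bin-edge splits."""
    idx = np.clip(np.floor(values * bins).astype(int), 0, bins - 1)
    hist = np.bincount(idx.ravel(), minlength=bins).astype(float)
    centers = (np.arange(bins) + 0.5) / bins
    best_k, best_var = None, -1.0
    for k in range(bins - 1):
        w0 = hist[: k + 1].sum()
        w1 = hist[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
            mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
            var = (w0 / hist.sum()) * (w1 / hist.sum()) * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_k = var, k
    return (best_k + 1) / bins


def flood_fill_oracle(mask: np.ndarray, connectivity: int):
    """BFS labeling in row-major seed order; returns the label image."""
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), int)
    next_label = 1
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                q = deque([(r, c)])
                labels[r, c] = next_label
                while q:
                    y, x = q.popleft()
                    for dy, dx in neigh:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = next_label
                            q.append((ny, nx))
                next_label += 1
    return labels


def _shift_window(pad, r, dy, dx, h, w):
    return pad[r + dy : r + dy + h, r + dx : r + dx + w]


def morphology_oracle(mask: np.ndarray, footprint: np.ndarray):
    """Opening-then-closing from the definitions of erosion and dilation
    (zero padding outside the frame)."""
    offs = np.argwhere(footprint) - np.array(footprint.shape) // 2
    h, w = mask.shape
    r = int(np.abs(offs).max()) + 1

    def erode(m):
        pad = np.zeros((h + 2 * r, w + 2 * r), bool)
        pad[r : r + h, r : r + w] = m
        out = np.ones((h, w), bool)
        for dy, dx in offs:
            out &= _shift_window(pad, r, dy, dx, h, w)
        return out

    def dilate(m):
        pad = np.zeros((h + 2 * r, w + 2 * r), bool)
        pad[r : r + h, r : r + w] = m
        out = np.zeros((h, w), bool)
        for dy, dx in offs:
            out |= _shift_window(pad, r, -dy, -dx, h, w)
        return out

    opened = dilate(erode(mask))
    return erode(dilate(opened))


def _pm(values, channel="pni"):
    return ProbabilityMap(np.asarray(values, float), channel=channel)


# ---------------------------------------------------------------------------
# pyramid smoothing


class TestPyramidSmooth:
    def test_zero_levels_is_identity(self, rng):
        pm = _pm(rng.random((17, 23)))
        assert np.array_equal(pyramid_smooth(pm, 0).values, pm.values)

    def test_constant_map_is_preserved(self):
        pm = _pm(np.full((32, 32), 0.37))
        assert np.abs(pyramid_smooth(pm, 2).values - 0.37).max() < 1e-6

    def test_impulse_matches_loop_oracle_one_level(self):
        a = np.zeros((64, 64))
        a[32, 32] = 1.0
        out = pyramid_smooth(_pm(a), 1).values
        oracle = expand_oracle(reduce_oracle(a), (64, 64))
        assert np.abs(out - oracle).max() < 1e-12

    def test_odd_dims_two_levels_match_oracle(self, rng):
        a = rng.random((21, 27))
        out = pyramid_smooth(_pm(a), 2).values
        r1 = reduce_oracle(a)
        r2 = reduce_oracle(r1)
        oracle = expand_oracle(expand_oracle(r2, r1.shape), a.shape)
        assert np.abs(out - np.clip(oracle, 0, 1)).max() < 1e-12

    def test_too_small_for_levels_raises(self):
        with pytest.raises(SizingError):
            pyramid_smooth(_pm(np.zeros((4, 4))), 3)


# ---------------------------------------------------------------------------
# Otsu thresholding


class TestOtsu:
    def test_bimodal_split_lands_between_modes(self):
        values = np.array([0.1] * 50 + [0.9] * 50)
        t, degenerate = otsu_threshold(_pm(values.reshape(10, 10)))
        assert not degenerate
        assert 0.1 < t <= 0.9
        assert t == otsu_oracle(values)

    def test_uniform_map_is_degenerate(self):
        t, degenerate = otsu_threshold(_pm(np.full((5, 5), 0.42)))
        assert degenerate
        # the upper edge of the single occupied bin
        assert t == pytest.approx(np.ceil(0.42 * 256) / 256)

    def test_matches_exhaustive_search_on_random_maps(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 400))
            values = rng.random(n)
            if rng.random() < 0.5:  # add discrete clumps to force ties
                values = np.round(values * 8) / 8
            t, degenerate = otsu_threshold(_pm(values.reshape(1, -1)))
            if not degenerate:
                assert t == otsu_oracle(values), values


class TestBinarize:
    def test_all_zero_map_gives_empty_mask(self):
        assert not binarize_pni(_pm(np.zeros((8, 8)))).any()

    def test_two_level_map_keeps_only_the_high_mode(self):
        values = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.2, 0.95)
        mask = binarize_pni(_pm(values), const_threshold=0.5)
        assert np.array_equal(mask, values == 0.95)

    def test_raising_constant_threshold_never_adds_foreground(self, rng):
        pm = _pm(rng.random((32, 32)))
        prev = binarize_pni(pm, 0.3)
        for t in (0.5, 0.7, 0.9):
            cur = binarize_pni(pm, t)
            assert not (cur & ~prev).any()
            prev = cur

    def test_degenerate_otsu_falls_back_to_constant(self):
        mask = binarize_pni(_pm(np.full((4, 4), 0.8)), const_threshold=0.5)
        assert mask.all()


# ---------------------------------------------------------------------------
# nerve-mask extraction (morphological smoothing)


class TestExtractNerveMask:
    def test_no_smoothing_reduces_to_plain_threshold(self, rng):
        values = rng.random((40, 40))
        cfg = DecisionConfig(pyramid_levels=0, smoothing_radius_px=0)
        assert np.array_equal(extract_nerve_mask(_pm(values, "nerve"), cfg), values > 0.5)

    def test_opening_closing_matches_set_morphology_oracle(self, rng):
        from skimage.morphology import disk

        mask = rng.random((48, 48)) > 0.6
        mask[10:34, 8:30] = True
        cfg = DecisionConfig(pyramid_levels=0, smoothing_radius_px=3)
        got = extract_nerve_mask(_pm(mask.astype(float), "nerve"), cfg)
        assert np.array_equal(got, morphology_oracle(mask, disk(3)))

    def test_large_square_interior_survives_smoothing(self):
        values = np.zeros((60, 60))
        values[10:50, 10:50] = 1.0
        cfg = DecisionConfig(pyramid_levels=0, smoothing_radius_px=3)
        got = extract_nerve_mask(_pm(values, "nerve"), cfg)
        # the disk rounds the right-angle corners but preserves the body
        assert got[13:47, 13:47].all()
        assert not got[:10].any() and not got[:, :10].any()

    def test_isolated_pixel_removed_by_opening(self):
        values = np.zeros((20, 20))
        values[10, 10] = 1.0
        cfg = DecisionConfig(pyramid_levels=0, smoothing_radius_px=1)
        assert not extract_nerve_mask(_pm(values, "nerve"), cfg).any()


# ---------------------------------------------------------------------------
# connected components and the size filter


class TestComponents:
    def test_empty_mask_gives_no_components(self):
        assert extract_components(np.zeros((5, 5), bool)) == []

    def test_diagonal_pixels_depend_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(extract_components(mask, 8)) == 1
        assert len(extract_components(mask, 4)) == 2

    def test_solid_block_geometry(self):
        mask = np.zeros((10, 10), bool)
        mask[4:7, 2:5] = True
        (comp,) = extract_components(mask)
        assert comp.area_px2 == 9
        assert comp.bbox == (4, 2, 7, 5)
        assert comp.centroid == (5.0, 3.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(100):
            mask = rng.random((64, 64)) < rng.uniform(0.2, 0.6)
            comps = extract_components(mask, connectivity)
            oracle = flood_fill_oracle(mask, connectivity)
            labels = np.zeros_like(oracle)
            for comp in comps:
                labels[comp.pixels[:, 0], comp.pixels[:, 1]] = comp.label
            assert np.array_equal(labels, oracle)  # includes scan-order labels
            assert sum(c.area_px2 for c in comps) == int(mask.sum())


class TestSizeFilter:
    def _components(self, areas):
        return [
            Component(i + 1, a, (0, 0, 1, a), (0.0, 0.0), np.zeros((a, 2), int), (10, 10))
            for i, a in enumerate(areas)
        ]

    def test_cutoff_zero_removes_nothing(self):
        retained, removed = size_filter(self._components([1, 5, 100]), 0)
        assert removed == [] and len(retained) == 3

    def test_boundary_area_is_removed(self):
        retained, removed = size_filter(self._components([100, 21632, 21633]), 21632)
        assert [c.area_px2 for c in retained] == [21633]
        assert sorted(c.area_px2 for c in removed) == [100, 21632]

    def test_partition_property(self, rng):
        comps = self._components(rng.integers(1, 1000, size=50).tolist())
        retained, removed = size_filter(comps, 300)
        assert len(retained) + len(removed) == len(comps)
        assert {id(c) for c in retained}.isdisjoint({id(c) for c in removed})

    def test_calibrated_cutoff_removes_exactly_the_target_fraction(self):
        from pnikit.calibration import calibrate_cutoff

        comps = self._components(list(range(1, 101)))
        cutoff = calibrate_cutoff([c.area_px2 for c in comps], 0.10)
        assert cutoff == 90
        _, removed = size_filter(comps, cutoff)
        assert len(removed) == 90


# ---------------------------------------------------------------------------
# per-nerve inspection


def _comps_from(mask):
    return extract_components(np.asarray(mask, bool))


class TestAssignPni:
    def test_overlap_flags_nerve_at_zero_adjacency(self):
        nerve = np.zeros((20, 20), bool)
        nerve[5:10, 5:10] = True
        pni = np.zeros((20, 20), bool)
        pni[8:12, 8:12] = True
        (structure,) = assign_pni(_comps_from(nerve), _comps_from(pni), adjacency_px=0)
        assert structure.predicted_class == "PNI"
        assert structure.supporting_pni_components == [1]

    def test_chebyshev_distance_threshold_is_sharp(self):
        # nearest pixels (10,10) and (16,16): Chebyshev distance 6
        nerve = np.zeros((30, 30), bool)
        nerve[10, 10] = True
        pni = np.zeros((30, 30), bool)
        pni[16, 16] = True
        (at5,) = assign_pni(_comps_from(nerve), _comps_from(pni), adjacency_px=5)
        assert at5.predicted_class == "normal"
        (at6,) = assign_pni(_comps_from(nerve), _comps_from(pni), adjacency_px=6)
        assert at6.predicted_class == "PNI"

    def test_no_pni_components_leaves_all_nerves_normal(self):
        nerve = np.zeros((10, 10), bool)
        nerve[2:5, 2:5] = True
        structures = assign_pni(_comps_from(nerve), [], adjacency_px=5)
        assert [s.predicted_class for s in structures] == ["normal"]

    def test_one_component_can_support_multiple_nerves(self):
        nerves = np.zeros((20, 40), bool)
        nerves[5:8, 2:8] = True
        nerves[5:8, 20:26] = True
        pni = np.zeros((20, 40), bool)
        pni[9:11, 2:26] = True
        structures = assign_pni(_comps_from(nerves), _comps_from(pni), adjacency_px=2)
        assert [s.predicted_class for s in structures] == ["PNI", "PNI"]

    def test_dimension_mismatch_rejected(self):
        a = np.zeros((10, 10), bool)
        a[1, 1] = True
        b = np.zeros((12, 12), bool)
        b[1, 1] = True
        with pytest.raises(ShapeError):
            assign_pni(_comps_from(a), _comps_from(b))


# ---------------------------------------------------------------------------
# the full flow


class TestDecisionFlow:
    CFG = DecisionConfig(size_cutoff_px2=500)

    def test_all_zero_maps_give_no_nerves(self):
        z = np.zeros((64, 64))
        result = run_decision_flow(_pm(z, "nerve"), _pm(z, "pni"), self.CFG)
        assert result.nerves == []

    def test_recovers_planted_classes_on_synthetic_scene(self):
        scene = generate_scene(small_scene_spec(seed=21))
        nm, pm = scene_to_probability_maps(scene, blur_sigma=1.0, noise_sd=0.05, seed=9)
        result = run_decision_flow(nm, pm, self.CFG)
        truth = truth_from_scene(scene)
        assert len(result.nerves) == len(truth)
        # align by overlap: nerve regions are well separated, so match by bbox center
        for nv in result.nerves:
            cy, cx = nv.region.centroid
            rec = min(
                scene.nerve_records,
                key=lambda r: (cy - (r.bbox[0] + r.bbox[2]) / 2) ** 2
                + (cx - (r.bbox[1] + r.bbox[3]) / 2) ** 2,
            )
            expected = "PNI" if rec.truth_class == "PNI" else "normal"
            assert nv.predicted_class == expected

    def test_infinite_cutoff_removes_all_pni_calls(self):
        scene = generate_scene(small_scene_spec(seed=21))
        nm, pm = scene_to_probability_maps(scene, blur_sigma=1.0, noise_sd=0.05, seed=9)
        cfg = DecisionConfig(size_cutoff_px2=10**9)
        result = run_decision_flow(nm, pm, cfg)
        assert all(nv.predicted_class == "normal" for nv in result.nerves)
        assert result.pni_retained == []

    def test_flow_is_deterministic(self):
        scene = generate_scene(small_scene_spec(seed=3))
        nm, pm = scene_to_probability_maps(scene, seed=4)
        r1 = run_decision_flow(nm, pm, self.CFG)
        r2 = run_decision_flow(nm, pm, self.CFG)
        assert [n.predicted_class for n in r1.nerves] == [n.predicted_class for n in r2.nerves]
        assert np.array_equal(r1.pni_mask, r2.pni_mask)

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ShapeError):
            run_decision_flow(_pm(np.zeros((8, 8)), "nerve"), _pm(np.zeros((9, 9)), "pni"))
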