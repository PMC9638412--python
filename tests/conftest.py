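"""Shared fixtures: small synthetic scenes sized for fast unit tests."""

import numpy as np
import pytest

from pnikit.synthetic import NoiseSizeDist, SceneSpec, generate_scene


def small_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A compact 320x320 scene: 2 small nerves, tiny nests and noise, so the
    rule flow runs in milliseconds.  Pair with a reduced size cutoff."""
    params = dict(
        height_px=320,
        width_px=320,
        n_nerves=2,
        pni_fraction=0.5,
        nerve_axis_range_px=(16.0, 24.0),
        perineurium_thickness_px=4,
        tumor_cell_diameter_px=16.0,
        pni_nest_cells=(5, 7),
        n_noise_blobs=4,
        noise_size_dist=NoiseSizeDist("uniform", (("low", 60.0), ("high", 300.0))),
        n_perinerve_speckles=2,
        speckle_area_range_px2=(40.0, 120.0),
        noise_clearance_px=10.0,
        seed=seed,
    )
    params.update(overrides)
    return SceneSpec(**params)


def tiny_training_spec(seed: int = 0) -> SceneSpec:
    """A 64x64 single-nerve scene used as a training tile."""
    return SceneSpec(
        height_px=64,
        width_px=64,
        n_nerves=1,
        pni_fraction=0.0,
        nerve_axis_range_px=(10.0, 16.0),
        perineurium_thickness_px=3,
        tumor_cell_diameter_px=8.0,
        pni_nest_cells=(1, 2),
        n_noise_blobs=2,
        noise_size_dist=NoiseSizeDist("uniform", (("low", 40.0), ("high", 120.0))),
        n_perinerve_speckles=1,
        speckle_area_range_px2=(20.0, 60.0),
        noise_clearance_px=6.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_scene_spec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
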