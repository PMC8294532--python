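import numpy as np
import pytest

from srscount.simulate import SceneSpec, generate_paired_he, generate_srs_scene


@pytest.fixture(scope="session")
def small_scene():
    """A small clean scene: 40 isolated cells, no noise/artifacts."""
    spec = SceneSpec(height_px=768, width_px=768, n_cells=40,
                     overlap_fraction=0.0, n_artifacts=0, noise_sd=0.0,
                     he_shift_px_sd=0.0, he_dropout_prob=0.0, seed=42)
    srs, gt = generate_srs_scene(spec)
    return spec, srs, gt


@pytest.fixture(scope="session")
def paired_scene(small_scene):
    spec, srs, gt = small_scene
    he, gt_he = generate_paired_he(gt, spec)
    return spec, srs, gt, he, gt_he


@pytest.fixture
def rng():
    return np.random.default_rng(0)
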