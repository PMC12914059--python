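import numpy as np
import pytest

from deepuv import synth


@pytest.fixture(scope="session")
def static_scene():
    """One deterministic 3-class scene with ground truth."""
    cfg = synth.SceneConfig(n_cells=8, seed=3)
    frame, truth = synth.make_scene(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def subtype_scene():
    """One deterministic CD4-like/CD8-like scene plus rendered stack."""
    cfg = synth.SceneConfig(
        n_cells=8, class_mix={"cd4": 0.5, "cd8": 0.5}, seed=5, n_frames=500)
    frame, truth = synth.make_scene(cfg)
    stack = synth.render_stack(cfg, frame, truth)
    return cfg, frame, truth, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
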