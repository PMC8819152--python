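import numpy as np
import pytest

from psyllidet.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """256x256 scene with a handful of targets and its ground-truth mask."""
    cfg = SceneConfig(width=256, height=256, coverage=0.6, n_psyllids=3, n_flies=2, seed=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def paste_scene():
    """512x512 scene used by the copy-paste tests (5 original targets)."""
    cfg = SceneConfig(width=512, height=512, coverage=0.6, n_psyllids=3, n_flies=2, seed=1)
    return generate_scene(cfg)
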