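import numpy as np
import pytest

from giqe.pipeline import RunConfig, run_pipeline
from giqe.synthetic import SceneConfig, generate_synthetic_source


@pytest.fixture(scope="session")
def textured_rgb():
    """A deterministic mucosa-like RGB source image (224x256)."""
    return generate_synthetic_source(SceneConfig(seed=11)).pixels


@pytest.fixture(scope="session")
def textured_gray(textured_rgb):
    return textured_rgb @ np.array([0.299, 0.587, 0.114])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def pipeline_result():
    """The full default benchmark pipeline (70 sources, 1050 pairs, seed 42).

    Session-scoped: built once and shared by the bound/monotonicity/recovery
    checks.  Takes a few minutes; everything downstream reads from it.
    """
    return run_pipeline(RunConfig(seed=42))
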