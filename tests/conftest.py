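import numpy as np
import pytest
from hypothesis import settings

from imlseg import (
    ImageGeometry,
    PhantomSpec,
    PipelineConfig,
    make_phantom,
    make_scribbles,
    segment,
)

settings.register_profile("suite", derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 3-class, 2-channel phantom for unit-level pipeline tests."""
    spec = PhantomSpec(size=(20, 28, 28), seed=7)
    image, truth = make_phantom(spec)
    scribbles = make_scribbles(truth, fraction=0.03, seed=7)
    return image, truth, scribbles


@pytest.fixture(scope="session")
def default_phantom():
    """The full-scale default phantom used by the acceptance-level checks."""
    image, truth = make_phantom()
    scribbles = make_scribbles(truth, fraction=0.01, seed=42)
    return image, truth, scribbles


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    image, truth, scribbles = default_phantom
    return segment(image, scribbles, PipelineConfig())


@pytest.fixture()
def geom2d():
    return ImageGeometry(size=(16, 16), spacing=(1.0, 1.0), origin=(0.0, 0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
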