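import numpy as np
import pytest

from lbptop import LabelVolume, PhantomSpec, Volume, generate_cohort
from lbptop.lbp import LBPTOPExtractor


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.standard_normal((16, 16, 16)))


@pytest.fixture
def whole_mask():
    return LabelVolume(np.ones((16, 16, 16), dtype=np.int64))


@pytest.fixture(scope="session")
def strong_cohort():
    """Two-class texture cohort with a large smoothing-scale difference."""
    spec = PhantomSpec(shape=(20, 20, 20), class_effect=2.0, seed=101)
    volumes, y, atlas, labels = generate_cohort(spec, 20)
    return volumes, y, atlas, labels


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    volumes, y, atlas, _ = strong_cohort
    X = LBPTOPExtractor(atlas=atlas, radii_mm=(1.0,)).fit().transform(volumes)
    return X, y
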