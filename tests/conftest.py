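import numpy as np
import pytest
from hypothesis import settings

from pefkit.bmd_models import FitConfig
from pefkit.catalog import load_fixture
from pefkit.types import Compound, DoseResponseDataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def bap():
    return Compound(name="benzo[a]pyrene", short_form="BaP", formula="C20H12")


@pytest.fixture
def simple_dataset(bap):
    """Clean monotone quantal-linear-like incidence table."""
    return DoseResponseDataset(
        compound=bap, doses=[0.0, 1.0, 3.0, 10.0], n=[20, 20, 20, 20],
        incidence=[1, 5, 12, 19], publication_id="test", arm="comparator")


@pytest.fixture
def fast_fit_config():
    """Fewer restarts than the default, for unit-test speed."""
    return FitConfig(seed=0, n_starts=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
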