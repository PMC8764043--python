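import numpy as np
import pytest

from lohclass import fixtures
from lohclass.simulate import SimulationConfig
from lohclass.types import VariantClass


@pytest.fixture(scope="session")
def cohort_counts():
    return fixtures.load_cohort_counts()


@pytest.fixture(scope="session")
def family1():
    return fixtures.load_family1_samples()


@pytest.fixture(scope="session")
def classification_inputs():
    return fixtures.load_classification_inputs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pathogenic_only_config():
    """500 pathogenic-carrier samples in the detectable regime (purity >= 0.6)."""
    return SimulationConfig(
        n_variants_per_class=5,
        samples_per_variant=100,
        p_loss_wt_by_class={VariantClass.PATHOGENIC: 36 / 55},
        p_loss_variant_by_class={VariantClass.PATHOGENIC: 3 / 55},
        purity_range=(0.6, 0.9),
        read_depth=500,
        p_ngs=1.0,
        seed=7,
    )
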