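import numpy as np
import pytest

from crossbeta.cgdmd import CGModelParams
from crossbeta.scaffolds import build_cross_beta_scaffold
from crossbeta.scoring import AggregationScale, PotentialTable


@pytest.fixture(scope="session")
def class1_scaffold():
    return build_cross_beta_scaffold(1, 4, 7, 5.5, 12.0)


@pytest.fixture(scope="session")
def class8_scaffold():
    return build_cross_beta_scaffold(8, 4, 7, 5.5, 12.0)


@pytest.fixture(scope="session")
def potential():
    return PotentialTable.from_files()


@pytest.fixture(scope="session")
def agg_scale():
    return AggregationScale.from_file()


@pytest.fixture(scope="session")
def cg_params():
    return CGModelParams.from_files()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
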