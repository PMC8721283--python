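import warnings

import numpy as np
import pytest

from atlaskit import AtlasConfig, simulate_atlas
from atlaskit.qc import median_normalize, select_hvg
from atlaskit.synthetic import cluster_profiles

warnings.filterwarnings("ignore", message="input does not look standardized")
warnings.filterwarnings("ignore", message="smallest class has")


@pytest.fixture(scope="session")
def default_atlas():
    """The default synthetic atlas (5 clusters x 200 cells + planted doublets)."""
    return simulate_atlas(AtlasConfig(seed=1))


@pytest.fixture(scope="session")
def atlas_norm(default_atlas):
    """(norm, log_norm) of the default atlas."""
    return median_normalize(default_atlas)


@pytest.fixture(scope="session")
def atlas_hvgs(default_atlas, atlas_norm):
    _, log_norm = atlas_norm
    return select_hvg(log_norm, gene_names=list(default_atlas.var_names))


@pytest.fixture(scope="session")
def atlas_profiles(default_atlas):
    return cluster_profiles(default_atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
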