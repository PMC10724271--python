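import numpy as np
import pytest

from loopforge import contact
from loopforge.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default-condition simulated bundle, shared across tests."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_control(bundle):
    """(map, KR weights, expected profile) of the Control condition."""
    cmap = bundle.maps["Control"]
    w = contact.kr_balance(cmap)
    e = contact.expected_by_distance(cmap, w)
    return cmap, w, e


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)


def random_symmetric_counts(rng, n=50, scale=20.0):
    """Dense symmetric positive count-like matrix (strictly positive entries)."""
    a = rng.uniform(0.5, scale, size=(n, n))
    return np.triu(a) + np.triu(a, 1).T


def contact_map_from_dense(dense, chrom="chrT", resolution=25_000):
    import scipy.sparse as sp

    from loopforge.contact import ContactMap

    n = dense.shape[0]
    return ContactMap(chrom, resolution, n, sp.csr_matrix(np.triu(dense)))
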