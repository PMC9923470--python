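import numpy as np
import pytest

from invcline.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A quick dataset for IO/round-trip tests."""
    return simulate_dataset(SimConfig(seed=1, n_snps=120, n_contigs=24,
                                      n_ak_snps=12))


@pytest.fixture(scope="session")
def transect_bundle():
    """A full-size two-transect replicate shared across structure tests."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def karyotype_truth(transect_bundle):
    return np.array(transect_bundle.truth.karyotypes)
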