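import numpy as np
import pandas as pd
import pytest

from hccsvr.cohortsim import CohortConfig, simulate_cohort
from hccsvr.driver_catalog import load_catalogue
from hccsvr.mutsig import load_reference_signatures


@pytest.fixture(scope="session")
def default_bundle():
    """One full default cohort (seed 1), shared across tests."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced cohort for cheap end-to-end style checks."""
    cfg = CohortConfig(n_hcv_positive=8, n_svr_daa=4, n_svr_ifn=6, n_svr_other=1,
                       n_true_variants=25.0, artifact_rate=8.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def signatures():
    return load_reference_signatures()


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
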