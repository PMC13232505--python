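import numpy as np
import pytest

from transplantqg import glmm_engine as ge
from transplantqg import synthetic_data as sd


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced MCMC settings for unit tests."""
    return ge.MCMCConfig(n_burnin=200, thin=1, n_saved=200, rng_seed=7)


@pytest.fixture(scope="session")
def small_design():
    return sd.DesignSpec(species_label="A", n_sires=18, n_dams=18,
                         seeds_per_family_per_elevation=8, n_field_blocks=3)


@pytest.fixture(scope="session")
def gxe_params():
    """Ground truth with genuine sire structure on both traits."""
    dev = sd.exchangeable_cov(9.0, 0.6, 4)
    surv = sd.exchangeable_cov(0.2, 0.5, 4)
    cross = np.zeros((4, 4))
    cross[0, 3] = -0.8 * np.sqrt(dev[0, 0] * surv[3, 3])
    cov = sd.sire_cov_from_blocks(dev, surv, cross)
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    cov = (v * np.clip(w, 1e-9, None)) @ v.T
    return sd.GroundTruthParams(sire_cov=cov)


@pytest.fixture(scope="session")
def small_dataset(small_design, gxe_params):
    return sd.simulate_dataset(small_design, gxe_params, seed=42)
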