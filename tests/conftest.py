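import numpy as np
import pytest

from hicmrf import MCMCConfig, informative_prior, preset_config, simulate_dataset


@pytest.fixture(scope="session")
def noise_heavy_dataset():
    """The two-component simulation design: n=2500, alphas=(0.7, 0.3)."""
    return simulate_dataset(preset_config("noise-heavy", seed=42))


@pytest.fixture(scope="session")
def short_chain(noise_heavy_dataset):
    """A short but usable fit of the noise-heavy dataset (shared across tests)."""
    from hicmrf import run_mcmc

    ds = noise_heavy_dataset
    prior = informative_prior(ds.true_params.betas)
    cfg = MCMCConfig(iterations=600, burn_in=300, seed=7)
    return run_mcmc(ds.observations, ds.lattice, 2, prior, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
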