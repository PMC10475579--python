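import numpy as np
import pytest

from phenosel import TrialConfig, generate_trial, simulate_observations

STRONG_RG = ((1.0, 0.7, 0.9), (0.7, 1.0, 0.7), (0.9, 0.7, 1.0))


def strong_signal_config(seed=3):
    """h2 = 0.4 for height, genetic correlation 0.9 between height and the
    latent spectral channel."""
    return TrialConfig(
        seed=seed,
        rg_matrix=STRONG_RG,
        sigma2_family={"height": 0.16, "crown_area": 0.10, "latent": 0.16},
        sigma2_block={"height": 0.08, "crown_area": 0.10, "latent": 0.08},
        sigma2_residual={"height": 0.76, "crown_area": 0.80, "latent": 0.76},
    )


def null_signal_config(seed=5):
    """No genetic or environmental link between spectra and growth."""
    eye = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    return TrialConfig(seed=seed, rg_matrix=eye, env_corr=0.0)


@pytest.fixture(scope="session")
def default_config():
    return TrialConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_observations(generate_trial(default_config), default_config)


@pytest.fixture(scope="session")
def strong_dataset():
    cfg = strong_signal_config()
    return simulate_observations(generate_trial(cfg), cfg)


@pytest.fixture(scope="session")
def null_dataset():
    cfg = null_signal_config()
    return simulate_observations(generate_trial(cfg), cfg)


@pytest.fixture()
def small_config():
    return TrialConfig(
        n_sites=1,
        n_blocks_per_site=6,
        n_families=8,
        trees_per_block=8,
        mortality_rate=0.1,
        months=("Jun", "Jul"),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
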