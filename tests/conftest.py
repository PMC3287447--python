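import numpy as np
import pandas as pd
import pytest

from bipindex.config import DRIVERS, BipConfig
from bipindex.dataset import build_working_table
from bipindex.synthdata import SyntheticSpec, generate, make_worked_toy


@pytest.fixture(scope="session")
def toy():
    """The hand-computable six-country, two-driver fixture."""
    records, responses = make_worked_toy()
    return records, responses


@pytest.fixture(scope="session")
def toy_table(toy):
    records, _ = toy
    return build_working_table(records)


@pytest.fixture(scope="session")
def toy_config():
    # six countries: relax the complete-pair floor so screening can run
    return BipConfig(min_pairs=3)


@pytest.fixture(scope="session")
def small_synth():
    """One moderate synthetic dataset shared by read-only tests."""
    spec = SyntheticSpec(n_countries=100, noise_sd=0.05, missing_rate=0.05, rng_seed=11)
    records, truth = generate(spec)
    return build_working_table(records), truth


@pytest.fixture(scope="session")
def mixed_loading_spec():
    """All drivers load on both latents: every driver survives every screen."""
    return SyntheticSpec(
        n_countries=120, noise_sd=0.05, missing_rate=0.0, rng_seed=3,
        latent_map={d: 0.5 for d in DRIVERS},
    )


def make_series(values, index=None):
    return pd.Series(values, index=index, dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
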