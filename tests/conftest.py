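"""Shared fixtures: small synthetic ensembles generated at test time."""

from __future__ import annotations

import pytest

from savphen import synthetic
from savphen.types import SynthConfig

PLANTED_TERMS = (("sm", "log_map", 2, 0.12), ("dayl", "identity", 2, 0.01))
PLANTED_INTERCEPT = 0.22


@pytest.fixture(scope="session")
def noise_free_config() -> SynthConfig:
    return SynthConfig(
        n_sites=15,
        n_years=3,
        noise_sd=0.0,
        true_terms=PLANTED_TERMS,
        intercept=PLANTED_INTERCEPT,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_aligned(noise_free_config):
    """15-site aligned ensemble whose NDVI is an exact lagged function."""
    return synthetic.generate_aligned_ensemble(noise_free_config)


@pytest.fixture(scope="session")
def noisy_aligned():
    """Homogeneous ensemble with noise_sd = 0.02."""
    cfg = SynthConfig(
        n_sites=15,
        n_years=3,
        noise_sd=0.02,
        true_terms=PLANTED_TERMS,
        intercept=PLANTED_INTERCEPT,
        seed=11,
    )
    return synthetic.generate_aligned_ensemble(cfg)


@pytest.fixture(scope="session")
def small_raw_ensemble():
    """Three raw SiteRecords for preprocessing / IO tests."""
    cfg = SynthConfig(n_sites=3, n_years=2, noise_sd=0.01, seed=21)
    return synthetic.generate_ensemble(cfg)
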