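from dataclasses import replace

import pytest

from microprot.synthetic import SimConfig, simulate_proteome


@pytest.fixture(scope="session")
def config() -> SimConfig:
    """Small synthetic study: 20 proteins per component, default rules."""
    return SimConfig(seed=7, n_proteins_per_component=20)


@pytest.fixture(scope="session")
def noise_free_config(config) -> SimConfig:
    return replace(config, noise_cv={"default": 0.0}, shared_peptide_fraction=0.0)


@pytest.fixture(scope="session")
def proteome(config):
    return simulate_proteome(config)
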