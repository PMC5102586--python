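import numpy as np
import pandas as pd
import pytest

from propstrat.synthetic import GeneratorConfig, generate_sites, generate_trait_table


@pytest.fixture(scope="session")
def default_sites():
    """One medium confounded landscape shared across read-only tests."""
    cfg = GeneratorConfig(n_sites=2000, seed=11, confounding_strength=0.76)
    sites, truth = generate_sites(cfg)
    return sites, truth, cfg


@pytest.fixture(scope="session")
def traits():
    return generate_trait_table(n_families=40, n_guilds=4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_trait_table():
    """Three families, four guilds, fixed arbitrary affinities."""
    return pd.DataFrame({
        "family": ["A", "B", "C"],
        "score": [10.0, 6.0, 2.0],
        "guild_1": [0.7, 0.1, 0.25],
        "guild_2": [0.2, 0.3, 0.25],
        "guild_3": [0.1, 0.4, 0.25],
        "guild_4": [0.0, 0.2, 0.25],
    })
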