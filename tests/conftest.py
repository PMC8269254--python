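import numpy as np
import pandas as pd
import pytest

from metsynth import synthetic as syn


@pytest.fixture(scope="session")
def default_config() -> syn.SyntheticConfig:
    return syn.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config) -> syn.CohortData:
    return syn.generate_cohort(default_config)


@pytest.fixture(scope="session")
def count_table(default_config) -> syn.CountTable:
    return syn.generate_count_table(default_config)


@pytest.fixture(scope="session")
def metabolome(default_config) -> syn.MetabolomeBundle:
    return syn.generate_metabolome_and_map(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def toy_panel(rng) -> pd.DataFrame:
    """Small random marker panel on realistic scales."""
    n = 10
    return pd.DataFrame({
        m: np.abs(mean + sd * rng.standard_normal(n))
        for m, (mean, sd) in syn.MARKER_SCALES.items()
    }, index=[f"S{i}" for i in range(n)])
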