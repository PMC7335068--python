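import numpy as np
import pandas as pd
import pytest

from polyarch import (
    LifeTables,
    MixtureModel,
    make_reference_panel,
    simulate_effect_sizes,
    simulate_summary_stats,
)


@pytest.fixture(scope="session")
def small_panel():
    return make_reference_panel(n_snps=2000, n_chromosomes=22, seed=11)


@pytest.fixture(scope="session")
def polygenic_records(small_panel):
    """Summary statistics from a known single-slab architecture."""
    truth = MixtureModel(M=2000, pi_c=0.05, components=[(1.0, 1e-3)])
    arch = simulate_effect_sizes(small_panel, truth, seed=12)
    return simulate_summary_stats(arch, 20_000, 20_000, seed=13, n_jitter=0.1)


@pytest.fixture
def toy_life_tables():
    """Flat 1% incidence, 0.5% mortality on ages 30-80, three weight bins."""
    ages = np.arange(30, 81)
    weights = pd.DataFrame({
        "age_lo": [30, 35, 40],
        "age_hi": [34, 39, 44],
        "weight": [0.5, 0.3, 0.2],
    })
    return LifeTables(
        ages=ages,
        incidence=np.full(len(ages), 0.01),
        mortality=np.full(len(ages), 0.005),
        weights=weights,
    )
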