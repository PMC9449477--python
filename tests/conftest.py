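import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gsikit.assignment import AssignerConfig
from gsikit.panel import default_panel
from gsikit.simulate import (
    simulate_allele_frequencies,
    simulate_baseline_genotypes,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

POPS = ["6aN_Aut", "6aS", "6aN_Sp"]


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def specs(panel):
    """Three-population frequency specs at the standard differentiation level."""
    return simulate_allele_frequencies(
        3, panel, 0.5, seed=11, pop_names=POPS, n_individuals=300
    )


@pytest.fixture(scope="session")
def baseline(specs):
    """Standard synthetic baseline: 3 populations x 300, 45 markers, 1% missing."""
    return simulate_baseline_genotypes(specs, missing_rate=0.01, seed=12)


@pytest.fixture(scope="session")
def small_baseline(panel):
    """Quick 3 x 60 baseline for cheaper tests."""
    specs = simulate_allele_frequencies(
        3, panel, 0.5, seed=21, pop_names=POPS, n_individuals=60
    )
    return simulate_baseline_genotypes(specs, missing_rate=0.01, seed=22)


@pytest.fixture()
def l1_config():
    return AssignerConfig(level=1, n_train_per_group=200, n_pcs=20, n_iterations=5, seed=5)


def blob_dosage(seed, n_per_blob=50, d=30, k=3, sep=10.0):
    """K Gaussian blobs wrapped as a DosageMatrix-like input for clustering."""
    from gsikit.dapc import DosageMatrix

    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, (k, d))
    x = np.vstack([centers[i] + rng.normal(0, 1, (n_per_blob, d)) for i in range(k)])
    df = pd.DataFrame(x)
    return DosageMatrix(
        df - df.mean(), df.mean(), pd.Series(1.0, index=df.columns), list(range(len(df)))
    )
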