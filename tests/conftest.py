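import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsherit import (GeneticMap, GenotypeMatrix, panel_data,
                     simulate_phenotypes, simulate_ril_genotypes)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_panel(n=60, n_chrom=4, n_loci=240, length_cm=120.0, seed=0):
    """Small RIL panel for unit tests."""
    gmap = GeneticMap.uniform(n_chrom, n_loci, length_cm)
    return simulate_ril_genotypes(gmap, n, seed)


def sigma_for_signal(signal: float, m: int) -> float:
    """sigma_g giving an expected trait signal fraction Var(xi)/(Var(xi)+1)
    of ``signal`` for i.i.d. effects on m loci with unit-variance codes."""
    return float(np.sqrt(signal / (1.0 - signal) / m))


def random_genotypes(rng, n, m):
    """Unlinked {-1, +1} genotypes (no map), for generic model-fitting tests."""
    Z = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n, m))
    return GenotypeMatrix(Z, tuple(f"i{j}" for j in range(n)),
                          tuple(f"l{j}" for j in range(m)))


@pytest.fixture(scope="session")
def small_panel():
    return make_panel()


@pytest.fixture(scope="session")
def small_trait(small_panel):
    pheno, effects = simulate_phenotypes(small_panel, sigma_g=0.08,
                                         sigma_e=1.0, replicates=4, seed=7)
    return pheno, effects


@pytest.fixture(scope="session")
def small_data(small_panel, small_trait):
    from gsherit import average_replicates
    pheno, _ = small_trait
    y = average_replicates(pheno).values_for(small_panel.individual_ids)
    return panel_data(small_panel, y)
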