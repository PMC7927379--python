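import numpy as np
import pandas as pd
import pytest

from breedscan.genotypes import GenotypePanel
from breedscan.simulate import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 4-breed, 600-SNP panel with planted loci and missing calls."""
    return SimulationConfig(
        n_breeds=4,
        samples_per_breed=(12, 15, 10, 20),
        n_snps=600,
        fst=0.1,
        n_planted_per_breed=3,
        planted_delta=0.5,
        missing_rate=0.05,
        n_chromosomes=3,
        chrom_length_bp=1_000_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_panel(small_config)


@pytest.fixture
def small_panel(small_sim) -> GenotypePanel:
    return small_sim[0].copy()


def random_panel(
    n_samples: int = 20,
    n_snps: int = 50,
    n_breeds: int = 2,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """A complete random panel with guaranteed-polymorphic SNP columns."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.15, 0.85, size=n_snps)
    X = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    for j in range(n_snps):  # break any monomorphic column deterministically
        if np.ptp(X[:, j]) == 0:
            X[j % n_samples, j] = 1.0 if X[0, j] != 1.0 else 0.0
    if missing_rate > 0:
        X[rng.random(X.shape) < missing_rate] = np.nan
    snps = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(n_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    breeds = [f"B{i % n_breeds + 1}" for i in range(n_samples)]
    samples = pd.DataFrame({"id": [f"ind{i}" for i in range(n_samples)], "breed": sorted(breeds)})
    return GenotypePanel(X, snps, samples)
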