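import numpy as np
import pytest

from microgwas.io import KinshipMatrix
from microgwas.synthetic import (
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_taxa_counts,
)


def block_kinship(n: int, family_size: int = 5, within: float = 0.5) -> KinshipMatrix:
    """Sibship kinship: 1 on the diagonal, `within` inside families, 0 between."""
    fam = np.repeat(np.arange(int(np.ceil(n / family_size))), family_size)[:n]
    K = np.where(fam[:, None] == fam[None, :], within, 0.0)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, [f"ind{i:04d}" for i in range(n)])


def block_chol(K: KinshipMatrix) -> np.ndarray:
    return np.linalg.cholesky(K.values + 1e-9 * np.eye(K.n))


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=60,
        n_snps=400,
        n_families=12,
        family_size=5,
        n_taxa=20,
        reads_per_replicate=20_000,
        genome_length=2_000_000,
        peaks_per_tissue=400,
        planted_effects=[("g__taxon000", "snp00005", 1.0)],
        taxon_h2={"g__taxon001": 0.6},
        sex_effects={"g__taxon002": 1.0},
        age_effects={"g__taxon003": 0.5},
        seed=3,
    )


@pytest.fixture(scope="session")
def cohort(small_cfg):
    """Small simulated cohort shared across test modules (read-only)."""
    g, K = simulate_genotypes(small_cfg)
    cov = simulate_covariates(small_cfg, g.individuals)
    taxa, truth = simulate_taxa_counts(g, cov, small_cfg, true_kinship=K)
    return {"g": g, "K": K, "cov": cov, "taxa": taxa, "truth": truth, "cfg": small_cfg}
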