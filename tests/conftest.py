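import numpy as np
import pytest

from aquags import GenotypePanel, SimConfig, simulate_genotypes, simulate_phenotypes


def make_panel(dosages, chroms=None, positions=None):
    """Tiny hand-built panel helper."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if chroms is None:
        chroms = ["chr1"] * m
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    return GenotypePanel(
        dosages=dosages,
        individual_ids=[f"i{k}" for k in range(n)],
        snp_ids=[f"s{k}" for k in range(m)],
        chromosomes=np.asarray(chroms, dtype=object),
        positions_bp=np.asarray(positions),
    )


@pytest.fixture(scope="session")
def single_trait_cfg():
    """One polygenic trait at the cohort's scale (h2 = 0.38, 455 fish)."""
    return SimConfig(
        n_individuals=455, n_snps=2000, n_chromosomes=24,
        heritabilities=[0.38], trait_names=["BW"], trait_means=[130.71],
        trait_sds=[32.88], n_qtl=500, seed=20,
    )


@pytest.fixture(scope="session")
def single_trait_data(single_trait_cfg):
    panel = simulate_genotypes(single_trait_cfg)
    y, truth = simulate_phenotypes(panel, single_trait_cfg)
    return panel, y[:, 0], truth


@pytest.fixture(scope="session")
def hwe_panel():
    """Moderate panel in Hardy-Weinberg / linkage equilibrium."""
    cfg = SimConfig(n_individuals=500, n_snps=2000, n_chromosomes=10,
                    heritabilities=[0.5], trait_names=["T"], trait_means=[0.0],
                    trait_sds=[1.0], seed=33)
    return simulate_genotypes(cfg)
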