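import numpy as np
import pandas as pd
import pytest

from wssgblup import Pedigree, SimConfig, simulate_dataset


def random_pedigree(n: int, rng: np.random.Generator) -> Pedigree:
    """Random sorted pedigree: each animal's parents drawn from predecessors."""
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    n_founders = max(3, n // 5)
    for i in range(n_founders, n):
        if rng.random() < 0.85:
            sire[i], dam[i] = rng.choice(i, size=2, replace=False)
        elif rng.random() < 0.5:
            sire[i] = rng.integers(i)
    return Pedigree([f"a{i}" for i in range(n)], sire, dam)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared by the slower integration tests."""
    cfg = SimConfig(
        n_founders=60, n_generations=3, matings_per_generation=30,
        offspring_per_mating=2, n_chromosomes=2, snps_per_chromosome=150,
        n_qtl=3, h2=0.41, trait_type="continuous", n_cg=5, seed=11,
    )
    ped, geno, qtl, pheno, truth = simulate_dataset(cfg)
    return cfg, ped, geno, qtl, pheno, truth


@pytest.fixture()
def prepared_pheno(small_dataset):
    from wssgblup.pheno import prepare_phenotypes

    _, _, _, _, pheno, _ = small_dataset
    kept, _ = prepare_phenotypes(pheno, "continuous")
    return kept
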