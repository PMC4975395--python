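"""Simulation studies that probe the pipeline end to end.

Each study fixes its population design (the emulated study conditions) and
varies only the seed, so the same conditions are exercised identically by
the test suite, the acceptance script and the analysis drivers.
"""

from __future__ import annotations

import numpy as np

from .gwas import WssConfig, run_wssgblup, top_windows
from .pheno import prepare_phenotypes
from .pedigree import build_A_inverse
from .simulate import SimConfig, simulate_dataset
from .solver import ChainConfig, build_design, gibbs_threshold


def liability_h2_recovery(seeds, n_cycles: int = 20_000, burn_in: int = 2_000,
                          thin: int = 10) -> list[float]:
    """Posterior-mean liability heritability per seed, truth h2 = 0.30.

    ~2,000 animals with one binary record each (prevalence 0.186), purely
    polygenic liability, pedigree-only relationships; a scaled-down chain
    keeps each run to a few seconds.
    """
    out = []
    for seed in seeds:
        cfg = SimConfig(
            n_founders=200, n_generations=3, matings_per_generation=600,
            offspring_per_mating=1, n_chromosomes=1, snps_per_chromosome=50,
            n_qtl=0, h2=0.30, trait_type="binary_liability",
            liability_threshold_prevalence=0.186, n_cg=5, seed=seed,
        )
        ped, _, _, pheno, _ = simulate_dataset(cfg)
        kept, _ = prepare_phenotypes(pheno, "binary")
        model = build_design(kept, ped.ids, "binary",
                             cfg.h2 / (1 - cfg.h2), 1.0)
        model.trait_type = "binary"
        sol = gibbs_threshold(model, build_A_inverse(ped),
                              ChainConfig(n_cycles, burn_in, thin, seed=seed))
        out.append(sol.h2_posterior_mean)
    return out


def _qtl_study_config(seed: int) -> SimConfig:
    """5 QTL x 4% of additive variance among 5,000 SNPs; 1,000 genotyped
    of 3,000 pedigreed animals (two cohorts of 1,200 over 600 founders)."""
    return SimConfig(
        n_founders=600, n_generations=2, matings_per_generation=1200,
        offspring_per_mating=1, n_chromosomes=5, snps_per_chromosome=1000,
        founder_maf_range=(0.1, 0.5), morgans_per_chromosome=1.0,
        n_qtl=5, qtl_variance_fractions=(0.04,) * 5, h2=0.41,
        trait_type="continuous", n_cg=5, genotyped_fraction=1000 / 1200,
        seed=seed,
    )


def qtl_window_recovery(seeds, window_size: int = 100,
                        top_k: int = 10) -> list[tuple[int, int]]:
    """(QTL windows recovered in the top-k, QTL-bearing windows) per seed,
    read at iteration 2 of the weighted analysis."""
    out = []
    for seed in seeds:
        cfg = _qtl_study_config(seed)
        ped, geno, qtl, pheno, _ = simulate_dataset(cfg)
        kept, _ = prepare_phenotypes(pheno, "continuous")
        res = run_wssgblup(kept, ped, geno, trait_type="continuous",
                           h2=cfg.h2, config=WssConfig(window_size=window_size))
        rep = res.iteration(2).window_report
        top, _ = top_windows(rep, top_k)
        qtl_windows = {
            int(rep[(rep["start_snp"] <= qi) & (rep["end_snp"] >= qi)]
                ["window_index"].iloc[0])
            for qi in qtl.qtl_snp_indices
        }
        hits = len(qtl_windows & set(top["window_index"].astype(int)))
        out.append((hits, len(qtl_windows)))
    return out


def weight_amplification(seeds) -> list[bool]:
    """Whether the weight of a single 30%-variance QTL's SNP strictly grows
    from iteration 1 to iteration 2, per seed."""
    out = []
    for seed in seeds:
        cfg = SimConfig(
            n_founders=400, n_generations=2, matings_per_generation=800,
            offspring_per_mating=1, n_chromosomes=2, snps_per_chromosome=500,
            n_qtl=1, qtl_variance_fractions=(0.30,), h2=0.41,
            trait_type="continuous", n_cg=5, genotyped_fraction=0.75,
            seed=seed,
        )
        ped, geno, qtl, pheno, _ = simulate_dataset(cfg)
        kept, _ = prepare_phenotypes(pheno, "continuous")
        res = run_wssgblup(kept, ped, geno, trait_type="continuous",
                           h2=cfg.h2, config=WssConfig(window_size=100))
        qi = qtl.qtl_snp_indices[0]
        out.append(bool(res.iteration(2).d[qi] > res.iteration(1).d[qi]))
    return out
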