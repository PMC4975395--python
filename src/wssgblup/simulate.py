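"""Synthetic livestock data with the structure the single-step analysis assumes.

Generates a multi-generation pedigree, biallelic SNP genotypes by gene
dropping with Poisson crossovers, and phenotypes from an additive model:
planted QTL of chosen variance shares, an infinitesimal polygenic remainder
drawn down the pedigree, contemporary-group effects, and either a Gaussian
residual (continuous trait) or a unit-variance liability with a threshold
(binary trait).  Every run is fully determined by a single integer seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


@dataclass
class SimConfig:
    n_founders: int = 40
    n_generations: int = 2
    matings_per_generation: int = 20
    offspring_per_mating: int = 2
    n_chromosomes: int = 2
    snps_per_chromosome: int = 100
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    morgans_per_chromosome: float = 1.0
    n_qtl: int = 2
    qtl_variance_fractions: tuple[float, ...] | None = None
    h2: float = 0.41
    trait_type: str = "continuous"
    liability_threshold_prevalence: float = 0.186
    n_cg: int = 5
    cg_sd: float = 0.3
    age_slope: float = 0.01  # trait units per day, continuous trait only
    genotyped_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_chromosomes", "snps_per_chromosome",
                     "matings_per_generation", "offspring_per_mating", "n_cg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie in (0, 0.5]")
        if self.trait_type not in ("continuous", "binary_liability"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not (0.0 < self.liability_threshold_prevalence < 1.0):
            raise ValueError("liability_threshold_prevalence must be in (0, 1)")
        if not (0.0 < self.genotyped_fraction <= 1.0):
            raise ValueError("genotyped_fraction must be in (0, 1]")
        if self.qtl_variance_fractions is None:
            if self.n_qtl:
                # default: QTL jointly explain 30% of additive variance
                self.qtl_variance_fractions = tuple([0.3 / self.n_qtl] * self.n_qtl)
            else:
                self.qtl_variance_fractions = ()
        self.qtl_variance_fractions = tuple(self.qtl_variance_fractions)
        if len(self.qtl_variance_fractions) != self.n_qtl:
            raise ValueError("qtl_variance_fractions length must equal n_qtl")
        if sum(self.qtl_variance_fractions) > 1.0 + 1e-12:
            raise ValueError("qtl_variance_fractions must sum to <= 1")

    @property
    def m(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class QTLConfig:
    qtl_snp_indices: np.ndarray
    qtl_effects: np.ndarray

    def __post_init__(self) -> None:
        self.qtl_snp_indices = np.asarray(self.qtl_snp_indices, dtype=np.int64)
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if len(np.unique(self.qtl_snp_indices)) != len(self.qtl_snp_indices):
            raise ValueError("QTL indices must be unique")
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("QTL effects must be finite")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree: founders, then random matings.

    Sexes alternate within each generation cohort; each mating draws one
    male and one female from the previous generation (parents can repeat
    across matings, producing half-sib structure).
    """
    rng = _rng(config, "pedigree")
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    gen: list[int] = []
    sex: list[int] = []  # 0 male, 1 female
    for i in range(config.n_founders):
        ids.append(f"G0_{i:05d}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        gen.append(0)
        sex.append(i % 2)
    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == 0]
        females = [i for i in prev if sex[i] == 1]
        if not males or not females:
            raise ValueError("generation with a single sex; increase n_founders")
        cohort = []
        k = 0
        for _ in range(config.matings_per_generation):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            for _ in range(config.offspring_per_mating):
                ids.append(f"G{g}_{k:05d}")
                sire.append(s)
                dam.append(d)
                gen.append(g)
                sex.append(k % 2)
                cohort.append(len(ids) - 1)
                k += 1
        prev = cohort
    return Pedigree(ids, np.array(sire), np.array(dam), generation=np.array(gen))


def _meiosis(hap: np.ndarray, chrom_slices, cm_pos: np.ndarray,
             morgans: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent: Poisson crossovers, no interference."""
    gamete = np.empty(hap.shape[1], dtype=np.int8)
    for sl in chrom_slices:
        pos = cm_pos[sl]
        n_x = rng.poisson(morgans)
        start = rng.integers(2)
        if n_x == 0:
            gamete[sl] = hap[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, morgans * 100.0, size=n_x))
        # phase at each SNP = start + number of crossovers to its left
        phase = (start + np.searchsorted(xpos, pos)) % 2
        seg = hap[:, sl]
        gamete[sl] = np.where(phase == 0, seg[0], seg[1])
    return gamete


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene dropping: founder haplotypes from HWE, descendants by meiosis.

    Founder allele frequencies are drawn per SNP from founder_maf_range;
    the SNP map has strictly increasing 1-based bp positions within each
    chromosome, spaced to match the genetic length (1 cM ~ 1 Mb).
    """
    rng = _rng(config, "genotypes")
    m = config.m
    mc = config.snps_per_chromosome
    chrom_slices = [slice(c * mc, (c + 1) * mc) for c in range(config.n_chromosomes)]
    # map: equally spaced genetic positions with bp jitter
    cm_per_chrom = config.morgans_per_chromosome * 100.0
    cm_pos = np.empty(m)
    bp = np.empty(m, dtype=np.int64)
    chroms = np.empty(m, dtype=np.int64)
    for c, sl in enumerate(chrom_slices):
        cm = (np.arange(mc) + 0.5) * cm_per_chrom / mc
        cm_pos[sl] = cm
        gaps = rng.integers(1, int(2e6 * config.morgans_per_chromosome / mc) + 2, size=mc)
        bp[sl] = np.cumsum(gaps)
        chroms[sl] = c + 1
    snp_map = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"snp{c}_{j}" for c, j in zip(chroms, range(m))],
        "cm": cm_pos,
        "bp": bp,
    })

    lo, hi = config.founder_maf_range
    freqs = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5  # which allele is minor
    freqs = np.where(flip, freqs, 1.0 - freqs)

    n = pedigree.n
    haps = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            haps[i] = rng.random((2, m)) < freqs
        else:
            # simulated pedigrees always have both parents for non-founders
            haps[i, 0] = _meiosis(haps[s], chrom_slices, cm_pos,
                                  config.morgans_per_chromosome, rng)
            haps[i, 1] = _meiosis(haps[d], chrom_slices, cm_pos,
                                  config.morgans_per_chromosome, rng)
    dosages = haps.sum(axis=1)

    if config.genotyped_fraction < 1.0:
        last = pedigree.generation == pedigree.generation.max()
        cand = np.flatnonzero(last)
        k = max(1, int(round(config.genotyped_fraction * len(cand))))
        keep = np.sort(rng.choice(cand, size=k, replace=False))
    else:
        keep = np.arange(n)
    return GenotypeMatrix(
        sample_ids=[pedigree.ids[i] for i in keep],
        snp_map=snp_map,
        dosages=dosages[keep].astype(float),
    )


def draw_qtl(genotypes: GenotypeMatrix, config: SimConfig,
             sigma2_a: float) -> QTLConfig:
    """Place QTL on distinct SNPs and size their effects.

    Effect a_i is chosen so the QTL contributes fraction f_i of the additive
    variance under approximate linkage equilibrium: a_i^2 * 2 p_i q_i = f_i
    * sigma2_a, with p_i the realized allele frequency.  Signs are random.
    """
    rng = _rng(config, "qtl")
    if config.n_qtl == 0:
        return QTLConfig(np.array([], dtype=int), np.array([]))
    p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    usable = np.flatnonzero((p > 0.05) & (p < 0.95))
    if len(usable) < config.n_qtl:
        raise ValueError("not enough polymorphic SNPs to place QTL")
    idx = np.sort(rng.choice(usable, size=config.n_qtl, replace=False))
    f = np.asarray(config.qtl_variance_fractions)
    a = np.sqrt(f * sigma2_a / (2.0 * p[idx] * (1.0 - p[idx])))
    a *= rng.choice([-1.0, 1.0], size=config.n_qtl)
    return QTLConfig(idx, a)


def _polygenic_values(pedigree: Pedigree, sigma2_poly: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Infinitesimal breeding values down the pedigree.

    Founders ~ N(0, sigma2_poly); offspring = parent average + Mendelian
    sampling with variance sigma2_poly / 2 (inbreeding ignored here: the
    simulated matings keep F small).
    """
    n = pedigree.n
    u = np.zeros(n)
    noise = rng.standard_normal(n)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            u[i] = noise[i] * np.sqrt(sigma2_poly)
        else:
            pa = 0.5 * (u[s] + u[d])
            u[i] = pa + noise[i] * np.sqrt(0.5 * sigma2_poly)
    return u


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    qtl: QTLConfig,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes = CG effect (+ age covariate) + breeding value + residual.

    Returns (phenotype table, truth table).  The truth table carries every
    animal's true breeding value plus the QTL placement, for validation.

    Variance scales: for the continuous trait the phenotypic variance net
    of CG is 1, so sigma2_a = h2 and sigma2_e = 1 - h2.  For the binary
    trait the residual liability variance is fixed at 1, so sigma2_a =
    h2 / (1 - h2); the record is 1 iff liability exceeds the threshold
    implied by the target prevalence.
    """
    if float(np.sum(config.qtl_variance_fractions)) > 1.0 + 1e-12:
        raise ValueError("QTL variance fractions exceed total additive variance")
    rng = _rng(config, "phenotypes")
    if config.trait_type == "continuous":
        sigma2_a = config.h2
        sigma2_e = 1.0 - config.h2
    else:
        sigma2_a = config.h2 / (1.0 - config.h2) if config.h2 < 1 else np.inf
        sigma2_e = 1.0

    n = pedigree.n
    # QTL part: centered dosage x effect, for genotyped animals we know the
    # dosage; non-genotyped animals exist only when genotyped_fraction < 1,
    # in which case their QTL dosages come from the full gene drop rerun.
    geno_pos = np.array([pedigree.index_of(s) for s in genotypes.sample_ids])
    if len(geno_pos) != n:
        # regenerate full-population dosages deterministically (same streams)
        full = simulate_genotypes(pedigree, _full_geno_config(config))
        D_qtl = full.dosages[:, qtl.qtl_snp_indices]
    else:
        row_of_animal = np.empty(n, dtype=np.int64)
        row_of_animal[geno_pos] = np.arange(n)
        D_qtl = genotypes.dosages[row_of_animal][:, qtl.qtl_snp_indices]
    p_qtl = D_qtl.mean(axis=0) / 2.0
    u_qtl = (D_qtl - 2.0 * p_qtl) @ qtl.qtl_effects

    f_qtl = float(np.sum(config.qtl_variance_fractions))
    sigma2_poly = max(sigma2_a * (1.0 - f_qtl), 0.0)
    u_poly = _polygenic_values(pedigree, sigma2_poly, rng)
    tbv = u_qtl + u_poly

    cg = rng.integers(config.n_cg, size=n)
    # enforce minimum CG size of 4 by reassigning tiny groups to the largest
    counts = np.bincount(cg, minlength=config.n_cg)
    big = int(np.argmax(counts))
    for g in np.flatnonzero((counts > 0) & (counts < 4)):
        cg[cg == g] = big
    cg_eff = rng.standard_normal(config.n_cg) * config.cg_sd

    e = rng.standard_normal(n) * np.sqrt(sigma2_e)
    liability = cg_eff[cg] + tbv + e
    # the five CG fields are a deterministic, injective function of the
    # drawn group index so downstream CG formation recovers exactly n_cg
    records = pd.DataFrame({
        "animal_id": pedigree.ids,
        "yob": 2000 + cg % 3,
        "farm": 1 + cg % 2,
        "mg_birth": cg,
        "mg_wean": cg % 4,
        "mg_yearling": cg % 5,
    })
    if config.trait_type == "continuous":
        age = rng.uniform(300.0, 500.0, size=n)
        records["age_days"] = age
        records["trait"] = liability + config.age_slope * (age - 400.0)
    else:
        # threshold implied by the target prevalence, on the realized
        # liability scale (few CG draws shift the theoretical moments)
        thr = (liability.mean()
               + stats.norm.ppf(1.0 - config.liability_threshold_prevalence)
               * liability.std())
        records["trait"] = (liability > thr).astype(int)
    truth = pd.DataFrame({"animal_id": pedigree.ids, "tbv": tbv,
                          "u_qtl": u_qtl, "u_poly": u_poly})
    truth.attrs["qtl_snp_indices"] = qtl.qtl_snp_indices.tolist()
    truth.attrs["qtl_effects"] = qtl.qtl_effects.tolist()
    truth.attrs["sigma2_a"] = sigma2_a
    truth.attrs["sigma2_e"] = sigma2_e
    truth.attrs["age_slope"] = config.age_slope
    return records, truth


def _full_geno_config(config: SimConfig) -> SimConfig:
    import dataclasses
    return dataclasses.replace(config, genotyped_fraction=1.0)


def simulate_dataset(config: SimConfig):
    """Pedigree + genotypes + QTL + phenotypes in one deterministic call."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    if config.trait_type == "continuous":
        sigma2_a = config.h2
    else:
        sigma2_a = config.h2 / (1.0 - config.h2)
    qtl = draw_qtl(geno, config, sigma2_a)
    pheno, truth = simulate_phenotypes(ped, geno, qtl, config)
    return ped, geno, qtl, pheno, truth
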