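"""Weighted single-step GWAS: SNP back-solving, reweighting, window reports.

Given genomic breeding values a_g of the genotyped animals, per-SNP effects
are recovered as u = lambda D Z' G^{-1} a_g.  Squared effects scaled by
heterozygosity become the next iteration's SNP variance weights, normalized
so tr(D) stays equal to the SNP count (constant total additive variance),
and G is rebuilt with the new weights.  a_g itself is computed once and
never altered.  Results are summarized as the share of additive genetic
variance captured by consecutive windows of adjacent SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import (CenteredGenotypes, SNPWeightState, blend_G, build_G,
                      build_H_inverse, center_and_lambda, extract_A22,
                      invert_spd)
from .pedigree import Pedigree, build_A, build_A_inverse
from .solver import (BreedingValueSolution, ChainConfig, ModelSpec,
                     build_design, gibbs_threshold, solve_mme_linear)


@dataclass
class WssConfig:
    """Iteration and reporting settings (defaults follow the reference run)."""

    n_iterations: int = 3
    window_size: int = 150
    top_k: int = 10
    report_iteration: int = 2
    beta: float = 0.05
    window_method: str = "score_variance"  # or "weight_share"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (1 <= self.report_iteration <= self.n_iterations):
            raise ValueError("report_iteration must lie within 1..n_iterations")
        if self.window_size < 1 or self.top_k < 1:
            raise ValueError("window_size and top_k must be >= 1")


@dataclass
class IterationResult:
    t: int
    u_hat: np.ndarray
    d: np.ndarray
    window_report: pd.DataFrame


@dataclass
class WssResult:
    iterations: list[IterationResult]
    solution: BreedingValueSolution
    sigma2_a: float
    lam: float
    genotyped_index: np.ndarray
    snp_map: pd.DataFrame = field(default=None)

    def iteration(self, t: int) -> IterationResult:
        return self.iterations[t - 1]


def backsolve_snp_effects(
    cg: CenteredGenotypes,
    weights: SNPWeightState,
    G: np.ndarray,
    a_g: np.ndarray,
    G_inv: np.ndarray | None = None,
) -> np.ndarray:
    """u = lambda D Z' G^{-1} a_g.

    ``G`` must be the matrix built from this same Z, D and lambda.  If it
    is singular, callers should pass the blended matrix (and its inverse).
    """
    if len(a_g) != cg.n:
        raise ValueError("a_g length must equal the number of genotyped animals")
    if G_inv is None:
        G_inv = invert_spd(G, what="G")
    return cg.lam * weights.d * (cg.Z.T @ (G_inv @ a_g))


def update_weights(u_hat: np.ndarray, allele_freqs: np.ndarray) -> np.ndarray:
    """Raw next-iteration weights d_i = u_i^2 * 2 p_i (1 - p_i)."""
    u_hat = np.asarray(u_hat, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if u_hat.shape != p.shape:
        raise ValueError("u_hat and allele_freqs must have equal length")
    return u_hat**2 * 2.0 * p * (1.0 - p)


def normalize_weights(raw: np.ndarray, trace_reference: float | None = None,
                      iteration: int = 0) -> SNPWeightState:
    """Rescale weights so their sum equals tr(D(0)) = m."""
    raw = np.asarray(raw, dtype=float)
    if trace_reference is None:
        trace_reference = float(len(raw))
    total = raw.sum()
    if total <= 0:
        raise ValueError("all SNP weights are zero; nothing to renormalize")
    return SNPWeightState(raw * (trace_reference / total), iteration=iteration)


def _window_blocks(snp_map: pd.DataFrame, window_size: int):
    """Consecutive non-overlapping index blocks within each chromosome."""
    chrom = snp_map["chrom"].to_numpy()
    bp = snp_map["bp"].to_numpy()
    for c in pd.unique(chrom):
        ix = np.flatnonzero(chrom == c)
        if np.any(np.diff(bp[ix]) <= 0):
            raise ValueError(f"SNP map not sorted by bp within chromosome {c!r}")
        for start in range(0, len(ix), window_size):
            yield c, ix[start:start + window_size]


def window_variances(
    u_hat: np.ndarray,
    cg: CenteredGenotypes,
    snp_map: pd.DataFrame,
    window_size: int = 150,
    sigma2_a: float = 1.0,
    method: str = "score_variance",
) -> pd.DataFrame:
    """Percent of additive genetic variance per window of adjacent SNPs.

    score_variance (default): the empirical variance across genotyped
    animals of the window genomic score sum_{i in w} Z_i u_i, as a share of
    sigma2_a — this accounts for LD among the window's SNPs.  weight_share:
    the naive sum of per-SNP variances 2 p q u^2 instead.  Chromosome-
    terminal windows shorter than window_size are kept and flagged.
    """
    if method not in ("score_variance", "weight_share"):
        raise ValueError(f"unknown window method {method!r}")
    rows = []
    for w, (c, ix) in enumerate(_window_blocks(snp_map, window_size)):
        if method == "score_variance":
            score = cg.Z[:, ix] @ u_hat[ix]
            var = float(np.var(score, ddof=1)) if cg.n > 1 else 0.0
        else:
            p = cg.allele_freqs[ix]
            var = float(np.sum(2.0 * p * (1.0 - p) * u_hat[ix] ** 2))
        rows.append({
            "chrom": c,
            "window_index": w,
            "start_snp": int(ix[0]),
            "end_snp": int(ix[-1]),
            "start_bp": int(snp_map["bp"].iloc[ix[0]]),
            "end_bp": int(snp_map["bp"].iloc[ix[-1]]),
            "n_snps": len(ix),
            "short_window": len(ix) < window_size,
            "snp_ids": ",".join(snp_map["snp_id"].iloc[ix].astype(str)),
            "percent_variance": 100.0 * var / sigma2_a,
        })
    return pd.DataFrame(rows)


def top_windows(report: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, float]:
    """The k windows explaining the most variance, plus their summed percent.

    Ties break by (chromosome, first bp) ascending.  Asking for more
    windows than exist returns them all with a warning.
    """
    if len(report) == 0:
        raise ValueError("empty window report")
    if k > len(report):
        warnings.warn(f"k={k} exceeds the {len(report)} available windows",
                      stacklevel=2)
        k = len(report)
    ranked = report.sort_values(
        by=["percent_variance", "chrom", "start_bp"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    return ranked.reset_index(drop=True), float(ranked["percent_variance"].sum())


def run_wssgblup(
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    trait_type: str = "continuous",
    sigma2_a: float | None = None,
    sigma2_e: float | None = None,
    h2: float | None = None,
    config: WssConfig | None = None,
    chain: ChainConfig | None = None,
) -> WssResult:
    """Full weighted single-step GWAS.

    Iteration 1 uses D = I; breeding values are predicted once (direct MME
    solve for a continuous trait, threshold-model Gibbs for a binary one)
    and the genotyped sub-vector a_g is reused unchanged while D and G are
    updated for three (by default) back-solving iterations.

    Variance components are inputs: give (sigma2_a, sigma2_e) or h2, from
    which sigma2_a = h2, sigma2_e = 1 - h2 (continuous, unit phenotypic
    variance) or sigma2_a = h2/(1-h2), sigma2_e = 1 (binary liability).
    """
    config = config or WssConfig()
    if sigma2_a is None:
        if h2 is None:
            raise ValueError("give sigma2_a/sigma2_e or h2")
        if trait_type == "continuous":
            sigma2_a, sigma2_e = h2, 1.0 - h2
        else:
            sigma2_a, sigma2_e = h2 / (1.0 - h2), 1.0
    if sigma2_e is None:
        sigma2_e = 1.0

    geno_idx = np.array([pedigree.index_of(s) for s in genotypes.sample_ids])
    if genotypes.raw_codes and np.isnan(genotypes.dosages).any():
        genotypes = genotypes.impute_missing_mean()

    A = build_A(pedigree)
    A_inv = build_A_inverse(pedigree)
    A22 = extract_A22(A, geno_idx)
    A22_inv = invert_spd(A22, what="A22")
    cgm = center_and_lambda(genotypes.dosages)
    m = cgm.m

    tt = "binary" if trait_type in ("binary", "binary_liability") else "continuous"
    model = build_design(pheno, pedigree.ids, tt, sigma2_a, sigma2_e)
    model.trait_type = tt

    weights = SNPWeightState.identity(m)
    results: list[IterationResult] = []
    solution = None
    a_g = None
    sigma2_a_denom = sigma2_a
    for t in range(1, config.n_iterations + 1):
        weights.iteration = t
        G = build_G(cgm, weights)
        Gb = blend_G(G, A22, config.beta)
        G_inv = invert_spd(Gb, what="blended G")
        if t == 1:
            H_inv = build_H_inverse(A_inv, G_inv, A22_inv, geno_idx)
            if tt == "continuous":
                solution = solve_mme_linear(model, H_inv, genotyped_index=geno_idx)
            else:
                solution = gibbs_threshold(model, H_inv, chain or ChainConfig(),
                                           genotyped_index=geno_idx)
                sigma2_a_denom = solution.sigma2_a_posterior_mean
            a_g = solution.a_hat_genotyped
        u = backsolve_snp_effects(cgm, weights, Gb, a_g, G_inv=G_inv)
        report = window_variances(u, cgm, genotypes.snp_map,
                                  config.window_size, sigma2_a_denom,
                                  method=config.window_method)
        report.insert(0, "iteration", t)
        results.append(IterationResult(t, u, weights.d.copy(), report))
        weights = normalize_weights(update_weights(u, cgm.allele_freqs),
                                    m, iteration=t + 1)
    return WssResult(results, solution, sigma2_a_denom, cgm.lam, geno_idx,
                     snp_map=genotypes.snp_map)
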