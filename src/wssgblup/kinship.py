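"""Genomic and combined relationship matrices.

Implements the VanRaden construction of the (weighted) genomic relationship
matrix G = Z D Z' * lambda from centered allele dosages, the A22 extraction,
the blended G used to guarantee invertibility, and the single-step matrix

    H^{-1} = A^{-1} + [[0, 0], [0, G^{-1} - A22^{-1}]]

with the correction added into the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .pedigree import Pedigree, build_A


@dataclass
class CenteredGenotypes:
    """Centered dosage matrix Z = M - P with P_ij = 2 p_j, plus lambda.

    ``lam`` is the VanRaden normalizing constant 1 / sum_i 2 p_i (1 - p_i),
    the ratio of the per-SNP variance to the additive genetic variance.
    """

    Z: np.ndarray
    allele_freqs: np.ndarray
    lam: float

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class SNPWeightState:
    """Diagonal SNP variance weights D at iteration t.

    The trace reference tr(D(0)) = m is the normalization target that keeps
    total additive variance constant across reweighting iterations.
    """

    d: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("SNP weights must be non-negative")

    @property
    def trace_reference(self) -> float:
        return float(len(self.d))

    @classmethod
    def identity(cls, m: int) -> "SNPWeightState":
        return cls(np.ones(m), iteration=1)


def extract_A22(A_source, genotyped_index) -> np.ndarray:
    """Principal submatrix of A for the genotyped animals.

    ``A_source`` is either a dense A or a Pedigree (in which case A is
    built first); ``genotyped_index`` gives pedigree positions in
    genotype-matrix sample order.
    """
    if isinstance(A_source, Pedigree):
        A_source = build_A(A_source)
    idx = np.asarray(genotyped_index, dtype=np.int64)
    n = A_source.shape[0]
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("genotyped index outside pedigree range")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate ids in genotyped index")
    return A_source[np.ix_(idx, idx)]


def center_and_lambda(dosages: np.ndarray,
                      allele_freqs: np.ndarray | None = None) -> CenteredGenotypes:
    """Center dosages by twice the allele frequency; compute lambda.

    Allele frequencies default to the observed frequencies in the genotyped
    set itself; pass ``allele_freqs`` to center on reference (e.g. base
    population) frequencies instead.  Note that with data-estimated
    frequencies every column of Z sums to zero, so the raw G is always
    singular along the ones vector and needs blending before inversion.
    Monomorphic SNPs make lambda's summand vanish and must be removed by QC
    beforehand; missing dosages must already be imputed.
    """
    M = np.asarray(dosages, dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing dosages present; impute before centering")
    p = (M.mean(axis=0) / 2.0 if allele_freqs is None
         else np.asarray(allele_freqs, dtype=float))
    if allele_freqs is not None and p.shape != (M.shape[1],):
        raise ValueError("allele_freqs must give one frequency per SNP")
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = int(np.flatnonzero((p <= 0.0) | (p >= 1.0))[0])
        raise ValueError(
            f"monomorphic SNP at column {bad} (p={p[bad]:.3f}); run QC first"
        )
    Z = M - 2.0 * p
    lam = 1.0 / float(np.sum(2.0 * p * (1.0 - p)))
    return CenteredGenotypes(Z=Z, allele_freqs=p, lam=lam)


def build_G(cg: CenteredGenotypes, weights: SNPWeightState | None = None) -> np.ndarray:
    """Weighted genomic relationship matrix G = Z D Z' * lambda."""
    if weights is None:
        weights = SNPWeightState.identity(cg.m)
    if len(weights.d) != cg.m:
        raise ValueError(
            f"weight length {len(weights.d)} != number of SNPs {cg.m}"
        )
    G = (cg.Z * weights.d) @ cg.Z.T * cg.lam
    return 0.5 * (G + G.T)


def blend_G(G: np.ndarray, A22: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """Stabilized genomic matrix (1 - beta) G + beta A22.

    Raw G is singular whenever the genotyped count exceeds its effective
    rank; mixing in a small share of A22 restores full rank while barely
    moving the estimates.  beta = 0 returns G unchanged; beta = 1 would
    erase the genomic information and is rejected.
    """
    if not (0.0 <= beta < 1.0):
        raise ValueError(f"beta must be in [0, 1); got {beta}")
    if G.shape != A22.shape:
        raise ValueError("G and A22 must agree in shape and ordering")
    if beta == 0.0:
        return G
    return (1.0 - beta) * G + beta * A22


def build_H_inverse(
    A_inv: sparse.spmatrix,
    G_inv: np.ndarray,
    A22_inv: np.ndarray,
    genotyped_index,
) -> sparse.csr_matrix:
    """Assemble H^{-1} = A^{-1} + scatter(G^{-1} - A22^{-1}) sparsely.

    The dense correction lives only in the genotyped block; the result is
    returned as one CSR matrix (sparse pedigree part plus dense block).
    """
    idx = np.asarray(genotyped_index, dtype=np.int64)
    n = A_inv.shape[0]
    if idx.size == 0:
        return sparse.csr_matrix(A_inv)
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("genotyped index outside matrix range")
    corr = np.asarray(G_inv) - np.asarray(A22_inv)
    k = len(idx)
    if corr.shape != (k, k):
        raise ValueError("G_inv/A22_inv shape does not match genotyped index")
    rows = np.repeat(idx, k)
    cols = np.tile(idx, k)
    C = sparse.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    H_inv = (sparse.csr_matrix(A_inv) + C.tocsr()).tocsr()
    return H_inv


def invert_spd(M: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"{what} is not positive definite; blend with A22 (blend_G) first"
        ) from None
    inv = np.linalg.inv(L)
    return inv.T @ inv
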