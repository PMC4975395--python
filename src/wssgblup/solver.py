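"""Breeding-value prediction under the single-step animal model.

The model is y = X b + Z_a a + e with a ~ N(0, H sigma2_a) and
e ~ N(0, I sigma2_e).  For a continuous trait the mixed-model equations

    [X'X        X'Z      ] [b]   [X'y]
    [Z'X  Z'Z + H^{-1} k ] [a] = [Z'y],    k = sigma2_e / sigma2_a

are solved directly by a sparse factorization.  For a binary trait the
observed category is linked to an underlying normal liability; a Gibbs
sampler with data augmentation draws liabilities from truncated normals,
location effects from their scalar conditionals (one Gauss-Seidel sweep
per cycle), and the additive variance from its scaled inverse chi-square
conditional.  The residual liability variance is fixed at 1 because it is
not identifiable from binary data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import ndtr, ndtri

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not a or not callable(a[0]) else a[0]


@dataclass
class ChainConfig:
    """MCMC chain settings; defaults follow the reference analysis."""

    n_cycles: int = 300_000
    burn_in: int = 30_000
    thin: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be smaller than n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if retained_samples(self.n_cycles, self.burn_in, self.thin) < 1:
            raise ValueError("chain retains no samples; lengthen it or lower thin")


def retained_samples(n_cycles: int, burn_in: int, thin: int) -> int:
    """Number of post-burn-in samples kept at the given thinning interval."""
    if burn_in >= n_cycles:
        raise ValueError("burn_in must be smaller than n_cycles")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return (n_cycles - burn_in) // thin


@dataclass
class ModelSpec:
    """Design matrices and variance components for one trait."""

    y: np.ndarray
    X: np.ndarray
    Z_a: sparse.spmatrix
    sigma2_a: float
    sigma2_e: float
    trait_type: str = "continuous"
    fixed_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z_a.shape[0] != n:
            raise ValueError("X and Z_a must have one row per record")
        if self.sigma2_a <= 0:
            raise ValueError("sigma2_a must be positive")
        if self.trait_type == "binary" and abs(self.sigma2_e - 1.0) > 1e-12:
            raise ValueError("binary liability model requires sigma2_e = 1")
        if not self.fixed_names:
            self.fixed_names = [f"fixed_{j}" for j in range(self.X.shape[1])]


@dataclass
class BreedingValueSolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    genotyped_index: np.ndarray | None = None
    sigma2_a_posterior_mean: float | None = None
    sigma2_a_posterior_sd: float | None = None
    h2_posterior_mean: float | None = None
    a_hat_sd: np.ndarray | None = None
    n_retained: int | None = None
    sigma2_a_draws: np.ndarray | None = None  # retained chain, for diagnostics

    @property
    def a_hat_genotyped(self) -> np.ndarray:
        if self.genotyped_index is None:
            raise ValueError("no genotyped index attached to this solution")
        return self.a_hat[self.genotyped_index]


def build_design(
    pheno: pd.DataFrame,
    animal_order: list,
    trait_type: str,
    sigma2_a: float,
    sigma2_e: float,
) -> ModelSpec:
    """Incidence matrices from a prepared phenotype table.

    Fixed effects: intercept, CG dummies with the first level absorbed,
    and (continuous trait) the centered age-at-recording covariate.
    """
    pos = {a: i for i, a in enumerate(animal_order)}
    missing = [a for a in pheno["animal_id"] if a not in pos]
    if missing:
        raise ValueError(f"phenotyped animals missing from pedigree: {missing[:5]}")
    n = len(pheno)
    q = len(animal_order)
    rows = np.arange(n)
    cols = np.array([pos[a] for a in pheno["animal_id"]])
    Z_a = sparse.csr_matrix((np.ones(n), (rows, cols)), shape=(n, q))

    levels = sorted(pheno["cg_id"].unique())
    names = ["intercept"] + [f"cg:{lv}" for lv in levels[1:]]
    X = np.zeros((n, len(levels)))
    X[:, 0] = 1.0
    level_ix = {lv: j for j, lv in enumerate(levels)}
    for i, lv in enumerate(pheno["cg_id"]):
        j = level_ix[lv]
        if j > 0:
            X[i, j] = 1.0
    if trait_type == "continuous" and "age_days" in pheno.columns:
        age = pheno["age_days"].to_numpy(dtype=float)
        X = np.column_stack([X, age - age.mean()])
        names.append("age_days_centered")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design rank {rank} < {X.shape[1]} columns; "
            "confounded CG levels present"
        )
    return ModelSpec(pheno["trait"].to_numpy(dtype=float), X, Z_a,
                     sigma2_a, sigma2_e, trait_type, names)


def solve_mme_linear(model: ModelSpec, H_inv: sparse.spmatrix,
                     genotyped_index=None) -> BreedingValueSolution:
    """Direct sparse solve of the mixed-model equations (continuous trait)."""
    if model.trait_type == "binary":
        raise ValueError("use gibbs_threshold for the binary trait")
    X = sparse.csr_matrix(model.X)
    Z = sparse.csr_matrix(model.Z_a)
    k = model.sigma2_e / model.sigma2_a
    W = sparse.hstack([X, Z]).tocsr()
    p = X.shape[1]
    XtZ = (X.T @ Z).tocsr()
    C = sparse.bmat(
        [[(X.T @ X), XtZ],
         [XtZ.T, (Z.T @ Z) + sparse.csr_matrix(H_inv) * k]],
        format="csc",
    )
    rhs = W.T @ model.y
    sol = spsolve(C, rhs)
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(f"MME solve did not converge (rel. residual {resid:.2e})")
    gi = None if genotyped_index is None else np.asarray(genotyped_index)
    return BreedingValueSolution(b_hat=sol[:p], a_hat=sol[p:], genotyped_index=gi)


@njit(cache=True)
def _gibbs_sweep(Tdata, Tind, Tptr, Hdata, Hind, Hptr, p, k, r, theta, z):
    """One Gauss-Seidel sweep sampling each location effect from its scalar
    conditional N((r_j - C_{j,-j} theta_{-j}) / c_jj, 1 / c_jj)."""
    n = theta.shape[0]
    for j in range(n):
        s = 0.0
        cjj = 0.0
        for t in range(Tptr[j], Tptr[j + 1]):
            col = Tind[t]
            s += Tdata[t] * theta[col]
            if col == j:
                cjj += Tdata[t]
        if j >= p:
            jj = j - p
            for t in range(Hptr[jj], Hptr[jj + 1]):
                col = Hind[t]
                s += k * Hdata[t] * theta[p + col]
                if col == jj:
                    cjj += k * Hdata[t]
        mean = (r[j] - s + cjj * theta[j]) / cjj
        theta[j] = mean + z[j] / np.sqrt(cjj)


def _sample_liabilities(eta: np.ndarray, y: np.ndarray,
                        u: np.ndarray) -> np.ndarray:
    """Truncated-normal draws: l > 0 where y = 1, l <= 0 where y = 0."""
    alpha = ndtr(-eta)  # P(l <= 0 | eta)
    alpha = np.clip(alpha, 1e-12, 1.0 - 1e-12)
    cum = np.where(y > 0.5, alpha + u * (1.0 - alpha), u * alpha)
    return eta + ndtri(np.clip(cum, 1e-12, 1.0 - 1e-12))


def gibbs_threshold(model: ModelSpec, H_inv: sparse.spmatrix | None,
                    chain: ChainConfig, genotyped_index=None,
                    log_every: int | None = None) -> BreedingValueSolution:
    """Liability-threshold Gibbs sampler for a binary trait.

    The threshold is fixed at 0 with a free intercept (an equivalent
    parameterization of an estimated threshold); flat priors on fixed
    effects and a flat (nu = -2) scaled inverse chi-square prior on
    sigma2_a.  ``H_inv = None`` drops the genetic term entirely, reducing
    the sampler to a Bayesian probit — useful for validation.
    """
    y = model.y
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary trait records must be 0/1")
    X = sparse.csr_matrix(model.X)
    # warn about monomorphic CG columns: their effect drifts without data
    dense_X = model.X
    for j in range(1, dense_X.shape[1]):
        in_level = dense_X[:, j] == 1.0
        if in_level.any() and len(np.unique(y[in_level])) == 1:
            warnings.warn(
                f"fixed-effect level {model.fixed_names[j]!r} has no response "
                "variability; its estimate will drift (filter such CGs first)",
                stacklevel=2,
            )
    use_genetic = H_inv is not None
    if use_genetic and model.Z_a.shape[1] <= 2:
        raise ValueError("need more than 2 animals to sample sigma2_a (df = q - 2)")
    if use_genetic:
        Z = sparse.csr_matrix(model.Z_a)
        W = sparse.hstack([X, Z]).tocsr()
        Hc = sparse.csr_matrix(H_inv)
        q = Z.shape[1]
    else:
        W = X
        Hc = sparse.csr_matrix((0, 0))
        q = 0
    p = X.shape[1]
    T = (W.T @ W).tocsr()
    rng = np.random.default_rng(chain.seed)

    theta = np.zeros(p + q)
    sigma2_a = model.sigma2_a  # starting value
    n_keep = retained_samples(chain.n_cycles, chain.burn_in, chain.thin)
    sum_theta = np.zeros(p + q)
    sum_theta2 = np.zeros(p + q)
    s2a_draws = np.empty(n_keep)
    kept = 0
    nu = -2.0  # flat prior on sigma2_a

    for cycle in range(1, chain.n_cycles + 1):
        eta = W @ theta
        u = rng.random(len(y))
        liab = _sample_liabilities(eta, y, u)
        r = W.T @ liab
        z = rng.standard_normal(p + q)
        k = 1.0 / sigma2_a if use_genetic else 0.0
        _gibbs_sweep(T.data, T.indices, T.indptr,
                     Hc.data, Hc.indices, Hc.indptr,
                     p, k, r, theta, z)
        if use_genetic:
            a = theta[p:]
            ss = float(a @ (Hc @ a))
            df = q + nu
            sigma2_a = (ss) / rng.chisquare(df)
        if cycle > chain.burn_in and (cycle - chain.burn_in) % chain.thin == 0:
            sum_theta += theta
            sum_theta2 += theta * theta
            if use_genetic:
                s2a_draws[kept] = sigma2_a
            kept += 1

    mean = sum_theta / kept
    var = np.maximum(sum_theta2 / kept - mean**2, 0.0)
    gi = None if genotyped_index is None else np.asarray(genotyped_index)
    s2a = s2a_draws[:kept] if use_genetic else np.array([])
    return BreedingValueSolution(
        b_hat=mean[:p],
        a_hat=mean[p:],
        genotyped_index=gi,
        sigma2_a_posterior_mean=float(s2a.mean()) if use_genetic else None,
        sigma2_a_posterior_sd=float(s2a.std(ddof=1)) if use_genetic else None,
        h2_posterior_mean=float((s2a / (s2a + 1.0)).mean()) if use_genetic else None,
        a_hat_sd=np.sqrt(var[p:]) if use_genetic else None,
        n_retained=kept,
        sigma2_a_draws=s2a if use_genetic else None,
    )
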