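"""Iterative genotype quality control.

SNP filters (applied in a fixed order: non-autosomal, duplicate map
position, HWE, MAF, quality score, call frequency) and sample filters
(call rate, duplicate samples) alternate until a full round removes
nothing, mirroring array-QC practice where dropping bad samples can push a
SNP's call frequency below threshold and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

SNP_RULES = ("non_autosomal", "same_position", "hwe", "maf", "quality", "call_rate")
SAMPLE_RULES = ("sample_call_rate", "duplicate_sample")


@dataclass
class QCThresholds:
    hwe_p_min: float = 1e-5
    maf_min: float = 0.02
    snp_quality_min: float = 0.15
    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.90
    exclude_non_autosomal: bool = True
    exclude_same_position: bool = True
    max_autosome: int = 29  # cattle: chromosomes 1..29 are autosomes

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "snp_quality_min",
                     "snp_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def minor_allele_frequency(dosage_column: np.ndarray) -> float:
    """min(p, 1-p) with p the second-allele frequency among non-missing calls."""
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("all calls missing; handle via the call-rate rule")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value = sum of the conditional probabilities (given the allele
    counts) of all heterozygote counts that are no more probable than the
    observed one.  Monomorphic columns have a single attainable outcome and
    return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    # attainable heterozygote counts share the parity of n_rare
    het = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het.size <= 1:
        return 1.0
    hom_rare = (n_rare - het) // 2
    hom_common = n - het - hom_rare
    # log P(het | allele counts) up to a constant: multinomial / hypergeometric
    logp = (het * np.log(2.0)
            - gammaln(het + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het, n_Aa)]
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def apply_snp_filters(
    genotypes: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[np.ndarray, pd.DataFrame]:
    """One pass of the six SNP rules; returns (keep mask, exclusion table).

    A SNP failing several rules is logged once, under the first failing
    rule in the fixed order.  All members of a same-position group are
    removed (there is no principled keep rule for array duplicates).
    """
    m = genotypes.m
    D = genotypes.dosages
    reason = np.full(m, "", dtype=object)
    stat = np.full(m, np.nan)

    def flag(mask: np.ndarray, rule: str, stats_: np.ndarray | float) -> None:
        new = mask & (reason == "")
        reason[new] = rule
        stat[new] = np.asarray(stats_)[new] if np.ndim(stats_) else stats_

    chroms = genotypes.snp_map["chrom"]
    if thresholds.exclude_non_autosomal:
        numeric = pd.to_numeric(chroms, errors="coerce")
        non_auto = (numeric.isna() | (numeric < 1)
                    | (numeric > thresholds.max_autosome)).to_numpy()
        flag(non_auto, "non_autosomal", np.nan)
    if thresholds.exclude_same_position:
        dup = genotypes.snp_map.duplicated(subset=["chrom", "bp"], keep=False)
        flag(dup.to_numpy(), "same_position", np.nan)

    n_called = (~np.isnan(D)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        allele_sum = np.nansum(D, axis=0)
    # columns with zero calls fall to the call-rate rule
    callable_ = n_called > 0

    hwe_p = np.ones(m)
    for j in np.flatnonzero(callable_ & (reason == "")):
        hwe_p[j] = hwe_exact_test(*_genotype_counts(D[:, j]))
    flag(callable_ & (hwe_p < thresholds.hwe_p_min), "hwe", hwe_p)

    p = np.divide(allele_sum, 2.0 * n_called, out=np.zeros(m), where=callable_)
    maf = np.minimum(p, 1.0 - p)
    flag(callable_ & (maf < thresholds.maf_min), "maf", maf)

    if genotypes.quality is not None:
        flag(genotypes.quality < thresholds.snp_quality_min, "quality",
             genotypes.quality)

    call_rate = n_called / genotypes.n
    flag(call_rate < thresholds.snp_call_rate_min, "call_rate", call_rate)

    removed = reason != ""
    table = pd.DataFrame({
        "entity": "snp",
        "id": genotypes.snp_map["snp_id"][removed],
        "rule": reason[removed],
        "statistic": stat[removed],
    })
    return ~removed, table.reset_index(drop=True)


def apply_sample_filters(
    genotypes: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample call-rate and duplicate-sample rules.

    Duplicates (identical dosage vectors, missing pattern included) keep
    only the lexicographically smallest sample id — deterministic and
    independent of file order.
    """
    D = genotypes.dosages
    n = genotypes.n
    reason = np.full(n, "", dtype=object)
    stat = np.full(n, np.nan)

    call_rate = (~np.isnan(D)).sum(axis=1) / max(genotypes.m, 1)
    low = call_rate < thresholds.sample_call_rate_min
    reason[low] = "sample_call_rate"
    stat[low] = call_rate[low]

    groups: dict[bytes, list[int]] = {}
    key = np.nan_to_num(D, nan=9.0)
    for i in range(n):
        groups.setdefault(key[i].tobytes(), []).append(i)
    for members in groups.values():
        if len(members) > 1:
            keep = min(members, key=lambda i: str(genotypes.sample_ids[i]))
            for i in members:
                if i != keep and reason[i] == "":
                    reason[i] = "duplicate_sample"

    removed = reason != ""
    table = pd.DataFrame({
        "entity": "sample",
        "id": [genotypes.sample_ids[i] for i in np.flatnonzero(removed)],
        "rule": reason[removed],
        "statistic": stat[removed],
    })
    return ~removed, table.reset_index(drop=True)


@dataclass
class QCReport:
    rounds: list[pd.DataFrame] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        """Total passes, including the final confirming pass that removes nothing."""
        return len(self.rounds)

    @property
    def n_productive_rounds(self) -> int:
        """Passes that actually removed a SNP or sample."""
        return sum(len(t) > 0 for t in self.rounds)

    def to_frame(self) -> pd.DataFrame:
        if not self.rounds:
            return pd.DataFrame(columns=["round", "entity", "id", "rule", "statistic"])
        parts = []
        for r, tab in enumerate(self.rounds, start=1):
            t = tab.copy()
            t.insert(0, "round", r)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)


def iterative_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters then sample filters, repeated to a fixpoint.

    Terminates because every productive round strictly shrinks the matrix.
    Emptying the matrix entirely is an error naming the last rule fired.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    current = genotypes
    while True:
        snp_keep, snp_tab = apply_snp_filters(current, thresholds)
        current = current.subset(snp_keep=snp_keep)
        if current.m == 0:
            raise ValueError(
                f"QC removed every SNP (last rule: {snp_tab['rule'].iloc[-1]})"
            )
        sample_keep, sample_tab = apply_sample_filters(current, thresholds)
        current = current.subset(sample_keep=sample_keep)
        if current.n == 0:
            raise ValueError(
                f"QC removed every sample (last rule: {sample_tab['rule'].iloc[-1]})"
            )
        report.rounds.append(pd.concat([snp_tab, sample_tab], ignore_index=True))
        if len(snp_tab) == 0 and len(sample_tab) == 0:
            break
    return current, report
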