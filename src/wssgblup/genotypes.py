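"""Genotype matrix container shared by the simulator, QC and kinship stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAP_COLUMNS = ["chrom", "snp_id", "cm", "bp"]


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (n samples x m SNPs) plus its SNP map.

    dosages hold counts of the second allele in {0, 1, 2}, with np.nan for
    missing calls.  The map follows the PLINK .map column order
    (chrom, snp_id, cm, bp).  ``quality`` is an optional per-SNP score in
    [0, 1] standing in for an array calling metric such as GenCall.
    """

    sample_ids: list
    snp_map: pd.DataFrame
    dosages: np.ndarray
    quality: np.ndarray | None = None
    raw_codes: bool = True  # False once imputation has introduced real values
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} SNPs"
            )
        missing = list(set(MAP_COLUMNS) - set(self.snp_map.columns))
        if missing:
            raise ValueError(f"snp_map lacks columns {sorted(missing)}")
        if self.raw_codes:
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
            if not ok.all():
                bad = self.dosages[~ok][0]
                raise ValueError(f"dosage code {bad!r} not in {{0,1,2,missing}}")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != (self.m,):
                raise ValueError("quality must be one score per SNP")
        if not self._pos:
            self._pos = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.snp_map)

    def subset(self, sample_keep=None, snp_keep=None) -> "GenotypeMatrix":
        """Restrict to boolean/index selections of samples and/or SNPs."""
        si = np.arange(self.n) if sample_keep is None else np.asarray(sample_keep)
        mi = np.arange(self.m) if snp_keep is None else np.asarray(snp_keep)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if mi.dtype == bool:
            mi = np.flatnonzero(mi)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            snp_map=self.snp_map.iloc[mi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, mi)],
            quality=None if self.quality is None else self.quality[mi],
            raw_codes=self.raw_codes,
        )

    def impute_missing_mean(self) -> "GenotypeMatrix":
        """Replace remaining missing dosages by the SNP mean (2p).

        Mean imputation keeps the centered matrix Z centered and is the
        conventional post-QC fill before building G.
        """
        D = self.dosages.copy()
        means = np.nanmean(D, axis=0)
        nan_rows, nan_cols = np.nonzero(np.isnan(D))
        D[nan_rows, nan_cols] = means[nan_cols]
        return GenotypeMatrix(self.sample_ids, self.snp_map, D,
                              quality=self.quality, raw_codes=False)
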