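"""File formats, run configuration and provenance headers.

Formats are deliberately plain: pedigree and phenotype CSV, a
whitespace-delimited dosage matrix with a SNP-id header row, and a PLINK
.map-order map file (chrom, snp_id, cm, bp).  Unknown parents are coded 0;
missing genotypes are accepted as 5 (BLUPF90 convention) or NA.  Every
file this package writes starts with a comment header declaring the seed,
iteration and a hash of the configuration, so any output can be traced to
the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import MAP_COLUMNS, GenotypeMatrix
from .pedigree import Pedigree
from .qc import QCThresholds
from .solver import ChainConfig
from .gwas import WssConfig

MISSING_CODES = {"5", "NA", "na", "nan", ""}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (flat key-value file friendly)."""

    pedigree_file: str = ""
    genotype_file: str = ""
    map_file: str = ""
    phenotype_file: str = ""
    out_dir: str = "wssgblup_out"
    trait_type: str = "continuous"
    h2: float | None = None
    sigma2_a: float | None = None
    sigma2_e: float | None = None
    window_size: int = 150
    n_iterations: int = 3
    report_iteration: int = 2
    top_k: int = 10
    beta: float = 0.05
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    chain: ChainConfig = field(default_factory=ChainConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        chain = ChainConfig(**raw.pop("chain", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(qc=qc, chain=chain, **raw)

    def wss_config(self) -> WssConfig:
        return WssConfig(
            n_iterations=self.n_iterations,
            window_size=self.window_size,
            top_k=self.top_k,
            report_iteration=self.report_iteration,
            beta=self.beta,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_header(config_hash: str, seed: int, iteration=None) -> str:
    it = "-" if iteration is None else str(iteration)
    return f"# wssgblup seed={seed} iteration={it} config={config_hash}\n"


def write_table(df: pd.DataFrame, path, config_hash: str = "none",
                seed: int = 0, iteration=None, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash, seed, iteration))
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------- pedigree

def write_pedigree(pedigree: Pedigree, path, **hdr) -> None:
    write_table(pedigree.to_frame(), path, sep=",", **hdr)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=",", comment="#", dtype=str)
    return Pedigree.from_frame(df)


# --------------------------------------------------------------- genotypes

def write_genotypes(geno: GenotypeMatrix, dosage_path, map_path, **hdr) -> None:
    """Dosage matrix (sample id + codes, 5 = missing) and PLINK-order map."""
    dosage_path, map_path = Path(dosage_path), Path(map_path)
    dosage_path.parent.mkdir(parents=True, exist_ok=True)
    codes = geno.dosages.copy()
    codes[np.isnan(codes)] = 5.0
    with open(dosage_path, "w") as fh:
        fh.write("id " + " ".join(geno.snp_map["snp_id"].astype(str)) + "\n")
        for sid, row in zip(geno.sample_ids, codes.astype(int)):
            fh.write(f"{sid} " + " ".join(map(str, row)) + "\n")
    geno.snp_map[MAP_COLUMNS].to_csv(map_path, sep="\t", index=False,
                                     header=False)


def read_genotypes(dosage_path, map_path, quality_path=None) -> GenotypeMatrix:
    snp_map = pd.read_csv(map_path, sep=r"\s+", header=None,
                          names=MAP_COLUMNS)
    sample_ids: list = []
    rows: list[np.ndarray] = []
    with open(dosage_path) as fh:
        header = fh.readline().split()
        snp_ids = header[1:]
        if snp_ids != list(snp_map["snp_id"].astype(str)):
            raise ValueError("dosage header SNP ids do not match the map file")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sample_ids.append(parts[0])
            vals = [np.nan if v in MISSING_CODES else float(v)
                    for v in parts[1:]]
            rows.append(np.array(vals))
    quality = None
    if quality_path is not None:
        q = pd.read_csv(quality_path, sep=r"\s+", header=None,
                        names=["snp_id", "quality"])
        quality = q.set_index("snp_id").loc[snp_ids, "quality"].to_numpy()
    return GenotypeMatrix(sample_ids, snp_map, np.vstack(rows),
                          quality=quality)


def write_matrix_triplets(matrix, animal_ids, path, **hdr) -> None:
    """Sparse relationship matrix (A^{-1}, H^{-1}, ...) as 3-column text:
    row id, column id, value — lower triangle only."""
    from scipy import sparse as sp

    coo = sp.coo_matrix(matrix)
    keep = coo.row >= coo.col
    df = pd.DataFrame({
        "row_id": [animal_ids[i] for i in coo.row[keep]],
        "col_id": [animal_ids[j] for j in coo.col[keep]],
        "value": coo.data[keep],
    })
    write_table(df, path, **hdr)


# -------------------------------------------------------------- phenotypes

def write_phenotypes(pheno: pd.DataFrame, path, **hdr) -> None:
    write_table(pheno, path, sep=",", **hdr)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=",", comment="#")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def write_truth(truth: pd.DataFrame, tbv_path, qtl_path, **hdr) -> None:
    write_table(truth, tbv_path, sep=",", **hdr)
    meta = {k: truth.attrs.get(k) for k in
            ("qtl_snp_indices", "qtl_effects", "sigma2_a", "sigma2_e",
             "age_slope")}
    Path(qtl_path).write_text(json.dumps(meta, indent=2))


# ------------------------------------------------------------ input wiring

def read_inputs(config: RunConfig):
    """Load and cross-validate the three input tables.

    The pedigree is re-sorted parents-first on load.  Every genotyped
    sample must have a pedigree record (the single-step H matrix needs
    pedigree relationships for all genotyped animals); phenotyped animals
    must also be in the pedigree.
    """
    ped = read_pedigree(config.pedigree_file)
    geno = read_genotypes(config.genotype_file, config.map_file)
    pheno = read_phenotypes(config.phenotype_file)
    known = set(map(str, ped.ids))
    orphan_geno = [s for s in geno.sample_ids if str(s) not in known]
    if orphan_geno:
        raise ValueError(
            f"genotyped ids absent from pedigree: {orphan_geno[:5]}"
        )
    orphan_pheno = [a for a in pheno["animal_id"] if str(a) not in known]
    if orphan_pheno:
        raise ValueError(
            f"phenotyped ids absent from pedigree: {orphan_pheno[:5]}"
        )
    return ped, geno, pheno
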