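"""End-to-end pipeline: phenotype prep -> genotype QC -> WssGBLUP -> reports."""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np

from . import io
from .gwas import run_wssgblup, top_windows
from .pheno import prepare_phenotypes
from .qc import iterative_qc
from .solver import ChainConfig

log = logging.getLogger("wssgblup")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: io.RunConfig):
    """Run every stage and write all artifacts under config.out_dir.

    Artifacts: phenotype audit log, QC report, breeding-value solutions,
    per-iteration SNP effects and window reports, the top-k window table
    (at the report iteration), and a run log with seed, versions and every
    default used.  Raises StageError naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.digest()
    hdr = dict(config_hash=h, seed=config.seed)

    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(name)s: %(message)s", force=False)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        import numpy, pandas, scipy  # noqa: F401  (versions for the log)
        log.info("config hash %s seed %d", h, config.seed)
        log.info("versions numpy=%s scipy=%s pandas=%s",
                 numpy.__version__, scipy.__version__, pandas.__version__)
        log.info("defaults window=%d iterations=%d report_iteration=%d "
                 "top_k=%d beta=%g", config.window_size, config.n_iterations,
                 config.report_iteration, config.top_k, config.beta)

        try:
            ped, geno, pheno_raw = io.read_inputs(config)
            log.info("inputs: %d pedigree, %d genotyped x %d SNPs, %d records",
                     ped.n, geno.n, geno.m, len(pheno_raw))
        except Exception as e:
            raise StageError("read_inputs", e)

        try:
            tt = "binary" if config.trait_type in ("binary", "binary_liability") \
                else "continuous"
            pheno, audit = prepare_phenotypes(pheno_raw, tt)
            io.write_table(audit, out / "pheno_audit.tsv", **hdr)
            log.info("pheno_prep: %d of %d records kept (%d removed)",
                     len(pheno), len(pheno_raw), len(audit))
        except Exception as e:
            raise StageError("pheno_prep", e)

        try:
            geno_qc, report = iterative_qc(geno, config.qc)
            io.write_table(report.to_frame(), out / "qc_report.tsv", **hdr)
            log.info("geno_qc: %d SNPs and %d samples remained after %d rounds",
                     geno_qc.m, geno_qc.n, report.n_rounds)
        except Exception as e:
            raise StageError("geno_qc", e)

        try:
            chain = ChainConfig(n_cycles=config.chain.n_cycles,
                                burn_in=config.chain.burn_in,
                                thin=config.chain.thin,
                                seed=config.seed)
            result = run_wssgblup(
                pheno, ped, geno_qc,
                trait_type=config.trait_type,
                sigma2_a=config.sigma2_a, sigma2_e=config.sigma2_e,
                h2=config.h2, config=config.wss_config(), chain=chain,
            )
        except Exception as e:
            raise StageError("wssgblup", e)

        try:
            write_outputs(result, ped, config, out, hdr)
        except Exception as e:
            raise StageError("report", e)
        log.info("done")
        return result
    finally:
        log.removeHandler(fh)
        fh.close()


def write_outputs(result, ped, config, out: Path, hdr: dict) -> None:
    import pandas as pd

    sol = result.solution
    fixed_tab = pd.DataFrame({
        "animal_id": "-",
        "effect": "fixed",
        "name": [f"fixed_{j}" for j in range(len(sol.b_hat))],
        "estimate": sol.b_hat,
        "posterior_sd": np.nan,
    })
    sol_tab = pd.DataFrame({
        "animal_id": list(ped.ids),
        "effect": "animal",
        "name": "breeding_value",
        "estimate": sol.a_hat,
        "posterior_sd": (sol.a_hat_sd if sol.a_hat_sd is not None
                         else np.full(len(sol.a_hat), np.nan)),
    })
    io.write_table(pd.concat([fixed_tab, sol_tab], ignore_index=True),
                   out / "solutions.tsv", **hdr)

    for it in result.iterations:
        eff = result.snp_map[["snp_id", "chrom", "bp"]].copy()
        eff["u_hat"] = it.u_hat
        eff["d"] = it.d
        eff["iteration"] = it.t
        io.write_table(eff, out / f"snp_effects_iter{it.t}.tsv",
                       iteration=it.t, **hdr)
        io.write_table(it.window_report, out / f"windows_iter{it.t}.tsv",
                       iteration=it.t, **hdr)

    rep = result.iteration(config.report_iteration)
    top, total = top_windows(rep.window_report, config.top_k)
    top = top.copy()
    top["cumulative_percent"] = top["percent_variance"].cumsum()
    io.write_table(top, out / "top_windows.tsv",
                   iteration=config.report_iteration, **hdr)
    # Manhattan-ready: the window report in genome order
    manhattan = rep.window_report.sort_values(["chrom", "start_bp"])
    io.write_table(manhattan, out / "manhattan.tsv",
                   iteration=config.report_iteration, **hdr)
    log.info("top-%d windows at iteration %d explain %.3f%% of sigma2_a",
             config.top_k, config.report_iteration, total)
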