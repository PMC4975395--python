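"""Phenotype preparation: trait coding, contemporary groups, record filters.

Contemporary groups (CG) collect animals raised under comparable conditions
— here the combination of year of birth, farm and the management groups at
birth, weaning and yearling.  Records are screened per CG: binary CGs with
no variability are dropped whole, continuous records outside the CG mean
+/- 3 SD are dropped, and any CG left with fewer than four records is
dropped.  Every removal is logged with its rule.
"""

from __future__ import annotations

import pandas as pd

CG_FIELDS = ["yob", "farm", "mg_birth", "mg_wean", "mg_yearling"]

RULE_MISSING_FIELD = "missing_cg_field"
RULE_NO_VARIABILITY = "cg_no_variability"
RULE_OUTLIER_3SD = "outside_3sd_of_cg"
RULE_SMALL_CG = "cg_fewer_than_4"


def code_early_pregnancy(calving_age_months: float) -> int:
    """Binary early-pregnancy code: 1 iff the heifer calved before 31 months.

    Callers are responsible for passing only heifers exposed at ~16 months.
    The boundary at exactly 31 months is a failure (success is strictly
    'less than 31 months').
    """
    if calving_age_months <= 0:
        raise ValueError(f"calving age must be positive, got {calving_age_months}")
    return 1 if calving_age_months < 31.0 else 0


def form_contemporary_groups(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign cg_id as the canonical concatenation of the five CG fields.

    Records missing any CG field are excluded and reported in the returned
    audit frame (record index, rule, detail).
    """
    missing_cols = [c for c in CG_FIELDS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack CG columns {missing_cols}")
    out = records.copy()
    bad = out[CG_FIELDS].isna().any(axis=1)
    audit = pd.DataFrame({
        "animal_id": out.loc[bad, "animal_id"],
        "rule": RULE_MISSING_FIELD,
        "detail": out.loc[bad, CG_FIELDS].isna().apply(
            lambda r: ",".join(c for c in CG_FIELDS if r[c]), axis=1),
    })
    out = out.loc[~bad].copy()
    if len(out):
        out["cg_id"] = out[CG_FIELDS].astype(str).agg("|".join, axis=1)
    else:
        out["cg_id"] = pd.Series(dtype=str)
    return out.reset_index(drop=True), audit.reset_index(drop=True)


def _drop(records: pd.DataFrame, mask, rule: str, detail: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    removed = records.loc[mask]
    audit = pd.DataFrame({
        "animal_id": removed["animal_id"],
        "rule": rule,
        "detail": detail,
    })
    return records.loc[~mask], audit


def filter_records(records: pd.DataFrame, trait_type: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the CG screening rules; return (kept records, audit log).

    Order: variability/outlier rule first, then minimum CG size, then one
    re-check of the size rule (the outlier rule can shrink a CG below 4).
    The +/- 3 SD band uses the within-CG mean and sample SD (n-1).
    """
    if trait_type not in ("continuous", "binary"):
        raise ValueError(f"trait_type must be continuous or binary, got {trait_type!r}")
    if "cg_id" not in records.columns:
        raise ValueError("assign cg_id first (form_contemporary_groups)")
    audits = []
    out = records.copy()
    if len(out) == 0:
        return out, pd.DataFrame(columns=["animal_id", "rule", "detail"])

    if trait_type == "binary":
        nun = out.groupby("cg_id")["trait"].transform("nunique")
        out, a = _drop(out, (nun <= 1).to_numpy(), RULE_NO_VARIABILITY,
                       "all records in CG share one category")
        audits.append(a)
    else:
        grp = out.groupby("cg_id")["trait"]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # sample SD; NaN for singleton CGs
        dev = (out["trait"] - mean).abs()
        outlier = (sd.notna() & (sd > 0) & (dev > 3.0 * sd)).to_numpy()
        out, a = _drop(out, outlier, RULE_OUTLIER_3SD, "outside CG mean +/- 3 SD")
        audits.append(a)

    for _ in range(2):  # size rule, then one re-check
        size = out.groupby("cg_id")["trait"].transform("size")
        small = (size < 4).to_numpy()
        if not small.any():
            break
        out, a = _drop(out, small, RULE_SMALL_CG, "CG with fewer than 4 records")
        audits.append(a)

    audit = pd.concat(audits, ignore_index=True) if audits else \
        pd.DataFrame(columns=["animal_id", "rule", "detail"])
    return out.reset_index(drop=True), audit


def prepare_phenotypes(records: pd.DataFrame, trait_type: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CG formation followed by record filtering; audits concatenated."""
    coded, a1 = form_contemporary_groups(records)
    tt = "binary" if trait_type in ("binary", "binary_liability") else "continuous"
    kept, a2 = filter_records(coded, tt)
    return kept, pd.concat([a1, a2], ignore_index=True)
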