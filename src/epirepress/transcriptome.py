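"""Differential gene expression: external result tables and a stand-in test.

The integration consumes a differential-expression table in the shape
produced by a bootstrap-aware quantification pipeline: per gene a
fold-change proxy ("beta", case vs control) and two FDR-corrected p-values
(likelihood-ratio and Wald tests).  A gene is called only when it passes
*both* tests at FDR < 0.05; down-regulated means significant with beta < 0.

``standin_de`` computes a documented substitute on a TPM-like matrix — a
Welch t-test on log2(TPM+1) whose BH-corrected q fills both q slots — so the
structural two-test AND-rule is preserved and a real external table drops in
unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["load_deg_table", "standin_de", "summarize_deg", "recompute_status"]

REQUIRED_COLUMNS = ("gene_id", "beta_fc", "q_lrt", "q_wald")


def recompute_status(deg: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """(Re)derive the down/up/unchanged call from q-values and fold change.

    Significant ⇔ q_lrt < fdr and q_wald < fdr; direction by the sign of
    beta_fc.  A significant gene with beta_fc = 0 has no direction and stays
    unchanged.  Status is never trusted from an input file.
    """
    sig = (deg["q_lrt"] < fdr) & (deg["q_wald"] < fdr)
    deg = deg.copy()
    deg["status"] = np.where(sig & (deg["beta_fc"] < 0), "down",
                             np.where(sig & (deg["beta_fc"] > 0), "up", "unchanged"))
    return deg


def load_deg_table(path, fdr: float = 0.05) -> pd.DataFrame:
    """Parse a differential-expression TSV (gene_id, beta_fc, q_lrt, q_wald, ...).

    Raises with row numbers on missing columns, non-numeric q-values or
    duplicate genes; the status column is recomputed, never read.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("beta_fc", "q_lrt", "q_wald"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            rows = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col} at file rows {rows}")
        raw[col] = coerced
    dup = raw["gene_id"][raw["gene_id"].duplicated()]
    if len(dup):
        rows = [int(i) + 2 for i in dup.index[:5]]
        raise ValueError(f"{path}: duplicate gene ids at file rows {rows}")
    deg = raw.set_index("gene_id")
    if "mean_tpm_ctrl" not in deg.columns:
        deg["mean_tpm_ctrl"] = np.nan
    return recompute_status(deg, fdr)


def standin_de(tpm: pd.DataFrame, conditions: pd.Series,
               fdr: float = 0.05, tpm_min: float = 1.0) -> pd.DataFrame:
    """Stand-in differential expression on a gene × sample TPM matrix.

    Pooled-variance t-test per gene on log2(TPM+1) (at 3-vs-6 replicate sizes
    a per-group variance estimate has too few degrees of freedom to be
    useful); the BH-corrected q fills both the LRT and Wald slots; beta_fc is
    the case − control mean log2 difference.
    Genes whose control mean TPM is below ``tpm_min`` are flagged
    ``low_expressed``; all-zero genes are retained with p = 1.
    """
    conditions = conditions.reindex(tpm.columns)
    ctrl = list(conditions.index[conditions == "control"])
    case = list(conditions.index[conditions == "case"])
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(f"need ≥2 samples per condition, got {len(ctrl)}/{len(case)}")
    log2 = np.log2(tpm.to_numpy(dtype=float) + 1.0)
    ic = [tpm.columns.get_loc(s) for s in ctrl]
    ia = [tpm.columns.get_loc(s) for s in case]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log2[:, ia], log2[:, ic], axis=1, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    beta_fc = log2[:, ia].mean(axis=1) - log2[:, ic].mean(axis=1)
    mean_ctrl = tpm.iloc[:, ic].mean(axis=1).to_numpy()
    deg = pd.DataFrame({
        "beta_fc": beta_fc, "q_lrt": q, "q_wald": q, "p_value": p,
        "mean_tpm_ctrl": mean_ctrl,
        "low_expressed": mean_ctrl < tpm_min,
    }, index=tpm.index.rename("gene_id"))
    return recompute_status(deg, fdr)


def summarize_deg(deg: pd.DataFrame) -> dict:
    """Counts of down-, up-regulated and total differential genes."""
    n_down = int((deg["status"] == "down").sum())
    n_up = int((deg["status"] == "up").sum())
    return {"n_down": n_down, "n_up": n_up, "n_total": n_down + n_up}
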