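"""Signature scoring and correlation-based refinement.

The per-patient stress score ("MG score") is the negated mean of z-scored
expression over the signature genes: each gene is standardized across
patients so every gene contributes equally, the per-patient mean is taken
over genes, and the result is negated so that *higher* score means *lower*
expression of the (repressed) signature genes — i.e. more of the epigenetic
stress the signature tracks.

Refinement mirrors the pathway-correction step that shrinks a cell-line
signature to its clinically coherent core: each candidate gene's expression
is correlated with its pathway's module score across patients and kept only
when R > 0.25 with p < 0.05 for at least one of its pathways.  The module
score used for this correlation is the pathway *expression* score (the mean
z, i.e. the un-negated form): a gene that genuinely co-varies with its
pathway then shows a positive R, which is what the keep-rule tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gsea import GeneSetCollection

__all__ = ["ScoreVector", "signature_score", "pathway_module_scores", "refine_signature"]


@dataclass
class ScoreVector:
    """Per-patient signature score with bookkeeping of the genes used."""

    scores: pd.Series
    genes_used: list[str]
    n_excluded: int = 0


def _zscore_rows(expr: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.Index]:
    vals = expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    ok = (sd > 0).ravel()
    z = np.divide(vals - mean, sd, out=np.full_like(vals, np.nan), where=sd > 0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns), expr.index[~ok]


def signature_score(expr: pd.DataFrame, genes: Iterable[str],
                    ddof: int = 1, negate: bool = True) -> ScoreVector:
    """Negated mean z-scored expression over the signature genes.

    The matrix is restricted to the signature genes present in it; each gene
    row is z-scored across patients (sample sd, ``ddof=1``, by default);
    the per-patient mean over genes is negated.  Zero-variance genes have no
    defined z and are excluded from the mean (counted in ``n_excluded``).
    """
    genes = [g for g in dict.fromkeys(genes)]
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("no signature gene found in the expression matrix")
    if expr.shape[1] < 2:
        raise ValueError("need ≥2 patients to z-score expression")
    sub = expr.loc[present]
    z, degenerate = _zscore_rows(sub, ddof=ddof)
    used = [g for g in present if g not in set(degenerate)]
    if not used:
        raise ValueError("all signature genes have zero variance")
    score = z.mean(axis=0, skipna=True)
    if negate:
        score = -score
    return ScoreVector(score.rename("score"), used, n_excluded=len(degenerate))


def pathway_module_scores(expr: pd.DataFrame, pathways: Iterable[str],
                          sets: GeneSetCollection, ddof: int = 1,
                          negate: bool = True) -> dict[str, ScoreVector]:
    """Signature score applied per pathway's member genes.

    Pathways with no member in the matrix are skipped with a warning.
    """
    out: dict[str, ScoreVector] = {}
    for name in pathways:
        members = sorted(sets[name].genes)
        try:
            out[name] = signature_score(expr, members, ddof=ddof, negate=negate)
        except ValueError:
            warnings.warn(f"pathway {name!r} has no usable gene in the matrix; skipped",
                          stacklevel=2)
    return out


def refine_signature(expr: pd.DataFrame, candidates: Sequence[str],
                     gene_pathways: Mapping[str, Iterable[str]],
                     sets: GeneSetCollection,
                     r_min: float = 0.25, p_max: float = 0.05,
                     ddof: int = 1) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates whose expression tracks their pathway module score.

    For each candidate gene and each pathway it belongs to, computes the
    Pearson correlation of the gene's expression with that pathway's
    expression module score (mean z over the pathway's members) across
    patients.  A gene is kept when R > ``r_min`` (strict) and p < ``p_max``
    for at least one of its pathways.  Constant genes have no defined
    correlation and are dropped with a log entry in the report.

    Returns ``(refined_gene_list, report)`` where the report has one row per
    gene-pathway pair with columns gene, pathway, r, p, kept.
    """
    module = pathway_module_scores(
        expr, sorted({p for ps in gene_pathways.values() for p in ps}),
        sets, ddof=ddof, negate=False)
    rows = []
    kept_genes: list[str] = []
    for gene in candidates:
        if gene not in expr.index:
            rows.append({"gene": gene, "pathway": None, "r": np.nan, "p": np.nan,
                         "kept": False, "note": "absent from matrix"})
            continue
        x = expr.loc[gene].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append({"gene": gene, "pathway": None, "r": np.nan, "p": np.nan,
                         "kept": False, "note": "constant expression"})
            continue
        gene_kept = False
        for pathway in gene_pathways.get(gene, []):
            if pathway not in module:
                continue
            y = module[pathway].scores.reindex(expr.columns).to_numpy()
            r, p = stats.pearsonr(x, y)
            kept = bool(r > r_min and p < p_max)
            gene_kept = gene_kept or kept
            rows.append({"gene": gene, "pathway": pathway, "r": r, "p": p,
                         "kept": kept, "note": ""})
        if gene_kept:
            kept_genes.append(gene)
    report = pd.DataFrame(rows, columns=["gene", "pathway", "r", "p", "kept", "note"])
    return kept_genes, report
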