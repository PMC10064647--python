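"""Meta-integration of differential methylation, expression and pathways.

Combines the per-CpG differential-methylation table with the
differential-expression calls to derive gene lists with an inverse
methylation/expression relationship, restricted to regulatory regions
(promoter, enhancer, or promoter-or-enhancer "mixed" probes):

- list 1: up-regulated AND regulatory-hypomethylated;
- list 2: down-regulated AND regulatory-hypermethylated — the
  epigenetically repressed genes, the focus of everything downstream;
- completeness lists for gene-body methylation in either direction.

Pathways significantly hypermethylated (positive NES on the Δβ ranking) and
significantly underexpressed (negative NES on the expression ranking) are
intersected into the epigenetically repressed pathways; the genes composing
them, intersected with list 2, yield the stress signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .gsea import GeneSetCollection
from .methylome import REGULATORY_REGIONS

__all__ = ["IntegrationResult", "gene_methylation_status", "build_lists",
           "epigenetically_repressed_pathways", "derive_signature"]


@dataclass
class IntegrationResult:
    list1_up_hypo: list[str] = field(default_factory=list)
    list2_down_hyper: list[str] = field(default_factory=list)
    body_up_hyper: list[str] = field(default_factory=list)
    body_down_hypo: list[str] = field(default_factory=list)
    conflicted: list[str] = field(default_factory=list)
    repressed_pathways: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)


def gene_methylation_status(dmc: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene region-wise hyper/hypo flags from CpG-level calls.

    A gene is ``hyper_regulatory`` when at least one of its CpGs in a
    promoter, enhancer or mixed assignment is called hyper (analogously
    ``hypo_regulatory``); body flags are computed separately from gene-body
    CpGs.  Genes with no differential CpG carry all-False flags.
    """
    assign = assignments[assignments["gene_id"].fillna("") != ""]
    merged = assign.merge(dmc[["status"]], left_on="probe_id", right_index=True)
    merged = merged[merged["status"] != "unchanged"]
    genes = pd.Index(sorted(assign["gene_id"].unique()), name="gene_id")
    flags = pd.DataFrame(False, index=genes,
                         columns=["hyper_regulatory", "hypo_regulatory",
                                  "hyper_body", "hypo_body"])
    if merged.empty:
        return flags
    regulatory = merged["region"].isin(REGULATORY_REGIONS)
    body = merged["region"] == "body"
    for col, mask in [("hyper_regulatory", regulatory & (merged["status"] == "hyper")),
                      ("hypo_regulatory", regulatory & (merged["status"] == "hypo")),
                      ("hyper_body", body & (merged["status"] == "hyper")),
                      ("hypo_body", body & (merged["status"] == "hypo"))]:
        hit = merged.loc[mask, "gene_id"].unique()
        flags.loc[flags.index.intersection(hit), col] = True
    return flags


def build_lists(flags: pd.DataFrame, deg: pd.DataFrame) -> IntegrationResult:
    """Intersect methylation flags with expression calls into the four lists.

    Genes that are both hyper- and hypomethylated in regulatory regions are
    conflicted: they are excluded from lists 1 and 2 and reported separately.
    """
    shared = flags.index.intersection(deg.index)
    f = flags.loc[shared]
    d = deg.loc[shared]
    down = d["status"] == "down"
    up = d["status"] == "up"
    conflict = f["hyper_regulatory"] & f["hypo_regulatory"]
    res = IntegrationResult(
        list1_up_hypo=sorted(shared[up & f["hypo_regulatory"] & ~conflict]),
        list2_down_hyper=sorted(shared[down & f["hyper_regulatory"] & ~conflict]),
        body_up_hyper=sorted(shared[up & f["hyper_body"]]),
        body_down_hypo=sorted(shared[down & f["hypo_body"]]),
        conflicted=sorted(shared[conflict]),
    )
    if not res.list1_up_hypo and not res.list2_down_hyper:
        warnings.warn("integration produced empty gene lists 1 and 2", stacklevel=2)
    return res


def epigenetically_repressed_pathways(meth_gsea: pd.DataFrame,
                                      expr_gsea: pd.DataFrame) -> list[str]:
    """Pathways hypermethylated (NES>0) AND underexpressed (NES<0), both significant."""
    shared = meth_gsea.index.intersection(expr_gsea.index)
    if shared.empty:
        raise ValueError("methylation and expression GSEA results share no gene sets")
    m = meth_gsea.loc[shared]
    e = expr_gsea.loc[shared]
    hyper = m["significant"] & (m["nes"] > 0)
    under = e["significant"] & (e["nes"] < 0)
    return sorted(shared[hyper & under])


def derive_signature(list2: list[str], repressed_pathways: list[str],
                     sets: GeneSetCollection, combine: str = "union") -> list[str]:
    """Genes composing the repressed pathways, intersected with list 2.

    ``combine`` chooses how "the genes composing these pathways" is read:
    ``union`` (default — the genes composing them collectively) or
    ``intersection`` (genes common to every repressed pathway, typically
    near-empty).  An empty signature is legal and only warned about.
    """
    if combine == "union":
        pathway_genes = sets.members(repressed_pathways)
    elif combine == "intersection":
        pathway_genes = sets.common_members(repressed_pathways)
    else:
        raise ValueError(f"combine must be 'union' or 'intersection', got {combine!r}")
    signature = sorted(pathway_genes & set(list2))
    if not signature:
        warnings.warn("derived signature is empty", stacklevel=2)
    return signature
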