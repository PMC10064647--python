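"""File formats and configuration: TSV matrices, GMT, RNK, YAML config.

All tabular artifacts are tab-separated with headers; gene and probe
identifiers are opaque strings.  Gene-set collections use the GMT dialect
(name TAB description TAB member...) with the TSG-A / OG-I class label in
the description field; an optional sidecar TSV (name TAB class) overrides
it.  Rankings use the two-column RNK dialect without a header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .gsea import GeneSet, GeneSetCollection, RankedList, SET_CLASSES

__all__ = [
    "parse_matrix_tsv", "write_matrix_tsv", "parse_gmt", "write_gmt",
    "parse_rnk", "write_rnk", "PipelineConfig", "write_manifest", "read_manifest",
]

FLOAT_FORMAT = "%.10g"  # fixed formatting => byte-identical reruns


def parse_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix whose first column is the row identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate row ids {list(dup[:5])}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index_label=index_label or df.index.name or "id")


def parse_gmt(path, class_sidecar=None, default_class: str = "TSG-A") -> GeneSetCollection:
    """Read a GMT gene-set file.

    The description column carries the TSG-A / OG-I class when it matches a
    known class label; otherwise ``default_class`` applies.  A sidecar TSV
    (set name TAB class, no header) overrides per-set classes.  Lines with no
    member gene are rejected with their line number.
    """
    classes: dict[str, str] = {}
    if class_sidecar is not None:
        side = pd.read_csv(class_sidecar, sep="\t", header=None, names=["name", "set_class"])
        classes = dict(zip(side["name"].astype(str), side["set_class"].astype(str)))
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"{path}:{lineno}: gene set with <1 member")
            name, desc = parts[0], parts[1]
            members = frozenset(p.strip() for p in parts[2:] if p.strip())
            cls = classes.get(name, desc if desc in SET_CLASSES else default_class)
            sets.append(GeneSet(name, members, set_class=cls, description=desc))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write GMT with the class label in the description column."""
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.set_class, *sorted(gs.genes)]) + "\n")


def parse_rnk(path) -> RankedList:
    """Read a two-column RNK file (gene TAB score, no header)."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>score', got {line!r}")
            gene, raw = parts
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if gene in scores:
                raise ValueError(f"{path}:{lineno}: duplicate gene {gene!r}")
            scores[gene] = value
    if not scores:
        raise ValueError(f"{path}: empty RNK file")
    return RankedList(scores)


def write_rnk(ranked: RankedList, path) -> None:
    with open(path, "w") as fh:
        for gene, score in ranked.scores.items():
            fh.write(f"{gene}\t{FLOAT_FORMAT % score}\n")


@dataclass
class PipelineConfig:
    """One YAML config binds every stage of a run.

    Paths point at the stage inputs; thresholds carry the printed cutoffs of
    the analysis (|Δβ| > 0.2 with adjusted p < 0.05 for differential CpGs,
    FDR < 0.05 for both differential expression tests and for GSEA calls,
    R > 0.25 with p < 0.05 for signature refinement, TPM ≥ 1 for the
    expressed-gene flag).
    """

    meth_m: str = ""
    meth_u: str = ""
    detection_p: str = ""
    annotation: str = ""
    expression: str = ""
    gene_sets: str = ""
    cohort_expression: str = ""
    cohort_clinical: str = ""
    sample_conditions: Mapping[str, str] = field(default_factory=dict)

    delta_beta: float = 0.2
    p_adj: float = 0.05
    de_fdr: float = 0.05
    gsea_fdr: float = 0.05
    refine_r: float = 0.25
    refine_p: float = 0.05
    tpm_min: float = 1.0
    weight_p: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    aggregation: str = "max_abs"
    signature_combine: str = "union"
    stratification: str = "tertiles"
    intensity_offset: float = 0.0

    def validate(self, check_paths: bool = True) -> None:
        for name in ("p_adj", "de_fdr", "gsea_fdr", "refine_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.delta_beta < 1.0:
            raise ValueError(f"delta_beta must be in (0, 1), got {self.delta_beta}")
        if not -1.0 < self.refine_r < 1.0:
            raise ValueError(f"refine_r must be in (-1, 1), got {self.refine_r}")
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be ≥100, got {self.n_perm}")
        if check_paths:
            for name in ("meth_m", "meth_u", "detection_p", "annotation",
                         "expression", "gene_sets", "cohort_expression",
                         "cohort_clinical"):
                p = getattr(self, name)
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path, check_paths: bool = True) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "set_size_range" in data:
            data["set_size_range"] = tuple(data["set_size_range"])
        cfg = cls(**data)
        cfg.validate(check_paths=check_paths)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["sample_conditions"] = dict(self.sample_conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = asdict(self)
        data["sample_conditions"] = dict(self.sample_conditions)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config, files: Mapping[str, str], truth_files: Mapping[str, str]) -> None:
    """Record a synthetic run: config, emitted files and ground-truth files."""
    payload = {"config": config, "files": dict(files), "ground_truth": dict(truth_files)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
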