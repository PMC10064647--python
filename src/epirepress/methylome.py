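"""Infinium-style methylation processing: raw intensities to differential CpGs.

The chain implemented here is the standard one for two-colour methylation
bead arrays reported as methylated (M) / unmethylated (U) intensities:

1. ``compute_beta`` — β = M / (U + M), the methylated fraction per CpG.
2. ``filter_probes`` — drop low-quality (detection p), cross-reactive,
   SNP-overlapping and sex-chromosome probes.
3. ``peak_correct`` — peak-based rescaling of type II probe M-values so the
   unmethylated / methylated density peaks line up with the type I chemistry.
4. ``diff_methylation`` — Welch t-test on M-values, Benjamini–Hochberg
   correction, Δβ from per-condition medians, and a hyper/hypo/unchanged call
   (|Δβ| > 0.2 and adjusted p < 0.05).
5. ``summarize_dmc`` — counts, percentages and region-class breakdown of the
   differentially methylated CpGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProbeAnnotation",
    "BetaMatrix",
    "compute_beta",
    "filter_probes",
    "peak_correct",
    "diff_methylation",
    "summarize_dmc",
    "beta_to_m",
    "m_to_beta",
    "REGULATORY_REGIONS",
    "REGION_CLASSES",
]

REGION_CLASSES = ("promoter", "enhancer", "body", "intergenic", "mixed")

#: Region classes counted as gene-regulatory: promoters overlap the TSS,
#: enhancers are atlas-linked to their target gene, and "mixed" probes are
#: promoter-or-enhancer depending on cell type, so they are kept regulatory.
REGULATORY_REGIONS = frozenset({"promoter", "enhancer", "mixed"})

BETA_CLIP = 1e-6  # avoids infinite M-values at β ∈ {0, 1}


def beta_to_m(beta: np.ndarray | pd.DataFrame, clip: float = BETA_CLIP):
    """logit2 transform: M = log2(β / (1 − β)), with β clipped away from {0,1}."""
    b = np.clip(beta, clip, 1.0 - clip)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: np.ndarray | pd.DataFrame):
    """Inverse of :func:`beta_to_m`: β = 2^M / (1 + 2^M)."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


@dataclass
class ProbeAnnotation:
    """Probe-level annotation for a methylation array.

    Parameters
    ----------
    probes
        DataFrame indexed by probe id with columns ``design_type`` ("I"/"II"),
        ``chrom``, and boolean flag columns ``cross_reactive``, ``snp_overlap``.
    assignments
        Long-format DataFrame with columns ``probe_id``, ``gene_id``,
        ``region`` (one of :data:`REGION_CLASSES`); a probe may map to several
        genes/regions, and intergenic rows carry an empty ``gene_id``.
    """

    probes: pd.DataFrame
    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids in annotation: {list(dup[:5])}")
        bad = set(self.assignments["region"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")
        nongenic = self.assignments["region"].ne("intergenic")
        if (self.assignments.loc[nongenic, "gene_id"].fillna("") == "").any():
            raise ValueError("non-intergenic assignment with empty gene_id")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index


@dataclass
class BetaMatrix:
    """β-values (probes × samples) with per-sample condition labels."""

    values: pd.DataFrame
    conditions: pd.Series  # sample -> "control" | "case"
    corrected: bool = False

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.conditions.unique()) - {"control", "case"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("β-values outside [0, 1]")

    def samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def compute_beta(M: pd.DataFrame, U: pd.DataFrame,
                 conditions: pd.Series | Mapping[str, str],
                 offset: float = 0.0) -> BetaMatrix:
    """β = M / (U + M + offset) from raw intensity matrices.

    The default has no intensity offset.  Cells with U + M = 0 are undefined
    and marked missing (NaN).
    """
    if M.shape != U.shape:
        raise ValueError(f"shape mismatch: M {M.shape} vs U {U.shape}")
    if not (M.index.equals(U.index) and M.columns.equals(U.columns)):
        raise ValueError("M and U must share probe index and sample columns")
    m = M.to_numpy(dtype=float)
    u = U.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative intensities")
    total = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / total, np.nan)
    values = pd.DataFrame(beta, index=M.index, columns=M.columns)
    return BetaMatrix(values, pd.Series(dict(conditions)) if not isinstance(conditions, pd.Series) else conditions.copy())


def filter_probes(beta: BetaMatrix, ann: ProbeAnnotation,
                  detection_p: pd.DataFrame,
                  detection_threshold: float = 0.05) -> tuple[BetaMatrix, pd.DataFrame]:
    """Remove low-quality and unreliable probes.

    A probe is dropped when any of these hold:

    - ``detection``: detection p > threshold in *any* sample (conservative
      any-sample policy);
    - ``cross_reactive`` / ``snp_overlap``: flagged in the annotation;
    - ``sex_chromosome``: located on chrX or chrY.

    Returns the filtered matrix and a removal log (probe_id × reason, one row
    per probe-reason pair).
    """
    probes = beta.values.index
    missing = probes.difference(ann.probes.index)
    if len(missing):
        raise ValueError(f"probes missing from annotation: {list(missing[:10])}"
                         + ("..." if len(missing) > 10 else ""))
    info = ann.probes.loc[probes]
    det = detection_p.reindex(index=probes, columns=beta.values.columns)

    reasons: dict[str, pd.Series] = {
        "detection": det.gt(detection_threshold).any(axis=1),
        "cross_reactive": info["cross_reactive"].astype(bool),
        "snp_overlap": info["snp_overlap"].astype(bool),
        "sex_chromosome": info["chrom"].isin(["chrX", "chrY", "X", "Y"]),
    }
    log_rows = [
        pd.DataFrame({"probe_id": probes[mask], "reason": name})
        for name, mask in reasons.items() if mask.any()
    ]
    log = (pd.concat(log_rows, ignore_index=True)
           if log_rows else pd.DataFrame(columns=["probe_id", "reason"]))
    drop = np.logical_or.reduce([mask.to_numpy() for mask in reasons.values()])
    kept = beta.values.loc[~drop]
    return BetaMatrix(kept, beta.conditions, corrected=beta.corrected), log


def _density_peaks(m: np.ndarray, gridsize: int = 1024) -> tuple[float, float] | None:
    """Highest local maximum of the M-value density on each side of M = 0.

    Gaussian KDE with Silverman bandwidth.  Returns (negative-side peak,
    positive-side peak) or None when either side lacks a peak — i.e. the
    distribution is not usably bimodal around zero.
    """
    m = m[np.isfinite(m)]
    if m.size < 10 or m.min() >= 0 or m.max() <= 0:
        return None
    kde = stats.gaussian_kde(m, bw_method="silverman")
    grid = np.linspace(m.min(), m.max(), gridsize)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = grid[1:-1][interior]
    heights = dens[1:-1][interior]
    neg = peaks < 0
    pos = peaks > 0
    if not neg.any() or not pos.any():
        return None
    return (peaks[neg][np.argmax(heights[neg])],
            peaks[pos][np.argmax(heights[pos])])


def peak_correct(beta: BetaMatrix, ann: ProbeAnnotation,
                 min_probes: int = 50) -> BetaMatrix:
    """Peak-based correction of the type II probe bias.

    Per sample: estimate the unmethylated (M < 0) and methylated (M > 0)
    density peaks of type I and type II probes separately, then rescale type II
    M-values linearly on each side of zero so its peaks coincide with the
    type I peaks; β is recovered by the inverse logit2.  Type I values are
    left untouched.  When either design type has fewer than ``min_probes``
    probes, or peak finding fails for a sample, that sample passes through
    unchanged with a warning.
    """
    design = ann.probes.loc[beta.values.index, "design_type"]
    is2 = (design == "II").to_numpy()
    n1, n2 = int((~is2).sum()), int(is2.sum())
    if n1 < min_probes or n2 < min_probes:
        warnings.warn(f"peak correction skipped: {n1} type I / {n2} type II probes "
                      f"(need ≥{min_probes} each)", stacklevel=2)
        return BetaMatrix(beta.values.copy(), beta.conditions, corrected=True)

    out = beta.values.to_numpy(dtype=float).copy()
    for j, sample in enumerate(beta.values.columns):
        col = out[:, j]
        m = beta_to_m(col)
        p1 = _density_peaks(m[~is2])
        p2 = _density_peaks(m[is2])
        if p1 is None or p2 is None:
            warnings.warn(f"sample {sample}: unimodal M-value distribution, "
                          "peak correction skipped for this sample", stacklevel=2)
            continue
        m2 = m[is2].copy()
        neg_scale = p1[0] / p2[0]
        pos_scale = p1[1] / p2[1]
        m2 = np.where(m2 < 0, m2 * neg_scale, m2 * pos_scale)
        corrected = m_to_beta(m2)
        nan_mask = ~np.isfinite(col[is2])
        corrected[nan_mask] = np.nan
        col[is2] = corrected
    values = pd.DataFrame(out, index=beta.values.index, columns=beta.values.columns)
    return BetaMatrix(values, beta.conditions, corrected=True)


def diff_methylation(beta: BetaMatrix,
                     delta_beta_threshold: float = 0.2,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-CpG differential methylation between case and control samples.

    - Δβ = median β(case) − median β(control);
    - p from a Welch two-sample t-test on M-values;
    - Benjamini–Hochberg adjustment across all tested probes;
    - status ``hyper`` iff Δβ > threshold and adjusted p < alpha,
      ``hypo`` iff Δβ < −threshold and adjusted p < alpha (strict
      inequalities on both sides), else ``unchanged``.

    Probes with zero within-group variance in both groups get p = 1.
    """
    ctrl = beta.samples("control")
    case = beta.samples("case")
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(f"need ≥2 samples per condition, got {len(ctrl)} control / {len(case)} case")
    if not beta.corrected:
        warnings.warn("running differential methylation on uncorrected β-values", stacklevel=2)

    b = beta.values
    m = beta_to_m(b.to_numpy(dtype=float))
    m_ctrl = m[:, [b.columns.get_loc(s) for s in ctrl]]
    m_case = m[:, [b.columns.get_loc(s) for s in case]]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(m_case, m_ctrl, axis=1, equal_var=False)
    degenerate = (m_case.var(axis=1) == 0) & (m_ctrl.var(axis=1) == 0)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)

    delta = (b[case].median(axis=1) - b[ctrl].median(axis=1)).to_numpy()
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    status = np.where((delta > delta_beta_threshold) & (p_adj < alpha), "hyper",
                      np.where((delta < -delta_beta_threshold) & (p_adj < alpha), "hypo",
                               "unchanged"))
    return pd.DataFrame(
        {"delta_beta": delta, "p_value": p, "p_adj": p_adj, "status": status},
        index=b.index.rename("probe_id"),
    )


@dataclass
class DmcSummary:
    """Counts and percentages of differential CpG calls."""

    n_dmc: int
    n_hyper: int
    n_hypo: int
    pct_hyper: float
    pct_hypo: float
    region_distribution: pd.DataFrame | None = field(default=None)

    def as_dict(self) -> dict:
        d = {"n_dmc": self.n_dmc, "n_hyper": self.n_hyper, "n_hypo": self.n_hypo,
             "pct_hyper": self.pct_hyper, "pct_hypo": self.pct_hypo}
        if self.region_distribution is not None:
            d["region_distribution"] = self.region_distribution.to_dict()
        return d


def summarize_dmc(dmc: pd.DataFrame, ann: ProbeAnnotation | None = None) -> DmcSummary:
    """Hyper/hypo counts and one-decimal percentages among DMCs.

    With an annotation, also reports how hyper- and hypomethylated CpGs
    distribute over region classes (a probe with several assignments counts
    once per distinct region class).  An empty DMC set yields zero counts and
    0.0 percentages rather than a division error.
    """
    n_hyper = int((dmc["status"] == "hyper").sum())
    n_hypo = int((dmc["status"] == "hypo").sum())
    n_dmc = n_hyper + n_hypo
    pct_hyper = round(100.0 * n_hyper / n_dmc, 1) if n_dmc else 0.0
    pct_hypo = round(100.0 * n_hypo / n_dmc, 1) if n_dmc else 0.0

    region = None
    if ann is not None and n_dmc:
        calls = dmc.loc[dmc["status"] != "unchanged", "status"]
        assign = ann.assignments[["probe_id", "region"]].drop_duplicates()
        merged = assign.merge(calls.rename("status"), left_on="probe_id", right_index=True)
        region = (merged.groupby(["status", "region"]).size().unstack(fill_value=0)
                  .reindex(columns=list(REGION_CLASSES), fill_value=0))
    return DmcSummary(n_dmc, n_hyper, n_hypo, pct_hyper, pct_hypo, region)
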