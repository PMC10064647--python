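"""Synthetic data with planted ground truth for the full integration chain.

Generates every input the pipeline consumes — methylation array intensities,
a TPM-like expression matrix, labeled gene-set collections and a patient
cohort with survival outcomes — so the chain from raw intensities to survival
stratification is testable end to end without any external download.

The emulated study design: a two-condition methylation array experiment with
3 control vs 6 case replicates; a bimodal β landscape (unmethylated mode near
0.1, methylated near 0.9); planted hypermethylated CpGs concentrated in the
promoter/enhancer regions of designated repressed genes; correlated planted
down-expression of those genes; gene sets enriched for them ("causal" sets);
and a cohort whose survival hazard depends on a latent per-patient stress
score that the planted signature genes load on.

Determinism: a single global seed fans out into independent per-generator
substreams, so each dataset can be regenerated on its own and two runs with
the same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gsea import GeneSet, GeneSetCollection
from .methylome import BetaMatrix, ProbeAnnotation, REGION_CLASSES

__all__ = ["SynthConfig", "GroundTruth", "make_methylation_dataset",
           "make_expression_dataset", "make_gene_sets", "make_cohort"]

_STREAMS = ("methylation", "expression", "gene_sets", "cohort")


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    n_probes: int = 20_000
    n_genes: int = 2_000
    n_ctrl_samples: int = 3
    n_case_samples: int = 6
    frac_hyper_probes: float = 0.05
    frac_hypo_probes: float = 0.01
    planted_delta_beta: float = 0.3
    beta_noise_conc: float = 500.0      # Beta concentration of replicate noise (per-sample β sd ≈ 0.02)
    baseline_conc: float = 20.0         # concentration of the baseline β mixture components
    frac_type2_probes: float = 0.85
    type2_compression: float = 0.8      # β' = 0.5 + s(β − 0.5) on type II probes
    frac_failed_probes: float = 0.005
    region_mix: Mapping[str, float] = field(default_factory=lambda: {
        "promoter": 0.20, "enhancer": 0.20, "body": 0.30,
        "intergenic": 0.20, "mixed": 0.10})
    n_repressed_genes: int = 100
    expr_log2fc: float = 1.5
    expr_noise_sd: float = 0.15         # log2-scale replicate noise
    n_gene_sets: int = 25
    n_causal_sets: int = 4
    causal_enrichment: float = 0.8      # fraction of causal-set members drawn from repressed genes
    set_size_range: tuple[int, int] = (20, 80)
    n_patients: int = 200
    cohort_loading: float = -0.5        # log2-expression change per latent-score unit (negative: repressed)
    cohort_noise_sd: float = 0.8
    hazard_coef: float = 0.8            # log-hazard per latent-score unit
    censor_rate: float = 0.3
    baseline_survival_months: float = 60.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_hyper_probes", "frac_hypo_probes", "frac_type2_probes",
                     "frac_failed_probes", "causal_enrichment", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_hyper_probes + self.frac_hypo_probes > 1.0:
            raise ValueError("frac_hyper_probes + frac_hypo_probes must be ≤ 1")
        for name in ("n_probes", "n_genes", "n_ctrl_samples", "n_case_samples",
                     "n_gene_sets", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_repressed_genes < 0 or self.n_causal_sets < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid set_size_range {self.set_size_range}")
        if hi > self.n_genes:
            raise ValueError(f"set_size_range {self.set_size_range} exceeds gene universe ({self.n_genes})")
        mix = sum(self.region_mix.get(r, 0.0) for r in REGION_CLASSES)
        if not np.isclose(mix, 1.0, atol=1e-6):
            raise ValueError(f"region_mix fractions must sum to 1, got {mix}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator, derived from the global seed."""
        i = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[i])


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    hyper_probe_ids: set[str] = field(default_factory=set)
    hypo_probe_ids: set[str] = field(default_factory=set)
    repressed_gene_ids: set[str] = field(default_factory=set)
    causal_set_names: set[str] = field(default_factory=set)
    true_patient_score: pd.Series | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(n)]


def _beta_component_params(mode: float, conc: float) -> tuple[float, float]:
    # Beta(a,b) with the requested mode: (a-1)/(a+b-2) = mode
    return 1.0 + mode * conc, 1.0 + (1.0 - mode) * conc


def make_methylation_dataset(cfg: SynthConfig):
    """Raw intensities (M, U), detection p-values, annotation and ground truth.

    Planted hypermethylated probes start on the unmethylated mode and shift
    by +``planted_delta_beta`` in case samples (hypo probes mirror this from
    the methylated mode); each designated repressed gene receives at least
    one planted hyper probe in a promoter or enhancer.  Type II probes get a
    linear compression of extreme β before intensities are emitted, so the
    peak-based correction has real work to do.

    Returns ``(M, U, detection_p, annotation, truth)``.
    """
    rng = cfg.rng("methylation")
    n = cfg.n_probes
    n_hyper = int(round(cfg.frac_hyper_probes * n))
    n_hypo = int(round(cfg.frac_hypo_probes * n))
    if cfg.n_repressed_genes > max(n_hyper, 0) and cfg.n_repressed_genes > 0:
        raise ValueError(
            f"cannot give each of {cfg.n_repressed_genes} repressed genes a planted "
            f"hyper probe with only {n_hyper} hyper probes; raise frac_hyper_probes")

    probes = _probe_ids(n)
    genes = _gene_ids(cfg.n_genes)
    n_repressed = cfg.n_repressed_genes if n_hyper > 0 else 0
    repressed = list(rng.choice(genes, size=n_repressed, replace=False)) if n_repressed else []

    # region + gene assignment; planted hyper probes are pushed into
    # regulatory regions, the first block pinned to the repressed genes
    region_names = list(REGION_CLASSES)
    region_p = np.array([cfg.region_mix.get(r, 0.0) for r in region_names])
    region = rng.choice(region_names, size=n, p=region_p / region_p.sum())
    gene_assign = rng.choice(genes, size=n)

    hyper_idx = np.arange(n_hyper)
    hypo_idx = np.arange(n_hyper, n_hyper + n_hypo)
    # hypo plants never sit on repressed genes: the planted truth would
    # otherwise contradict itself (conflicting regulatory calls on one gene)
    if n_hypo and repressed:
        non_repressed = [g for g in genes if g not in set(repressed)]
        for i in hypo_idx:
            if gene_assign[i] in set(repressed):
                gene_assign[i] = non_repressed[int(rng.integers(len(non_repressed)))]
    reg_bias = ["promoter", "enhancer", "mixed", "promoter", "enhancer"]
    for j, i in enumerate(hyper_idx):
        if j < n_repressed:
            # pinned block: guarantees every repressed gene one promoter/enhancer plant
            region[i] = ("promoter", "enhancer")[j % 2]
            gene_assign[i] = repressed[j]
            continue
        region[i] = reg_bias[j % len(reg_bias)]
        if repressed and rng.random() < 0.5:
            gene_assign[i] = repressed[rng.integers(len(repressed))]

    # baseline β: two-component mixture, modes near 0.1 and 0.9
    a_lo, b_lo = _beta_component_params(0.1, cfg.baseline_conc)
    a_hi, b_hi = _beta_component_params(0.9, cfg.baseline_conc)
    high_component = rng.random(n) < 0.5
    high_component[hyper_idx] = False   # hypermethylation starts unmethylated
    high_component[hypo_idx] = True     # hypomethylation starts methylated
    beta0 = np.where(high_component, rng.beta(a_hi, b_hi, size=n), rng.beta(a_lo, b_lo, size=n))

    delta = np.zeros(n)
    delta[hyper_idx] = cfg.planted_delta_beta
    delta[hypo_idx] = -cfg.planted_delta_beta
    target_case = beta0 + delta
    planted = np.zeros(n, dtype=bool)
    planted[hyper_idx] = True
    planted[hypo_idx] = True
    if planted.any():
        out_of_range = ((target_case[planted] < 0) | (target_case[planted] > 1)).mean()
        if out_of_range > 0.5:
            raise ValueError(
                f"planted_delta_beta={cfg.planted_delta_beta} pushes β outside [0,1] for "
                f"{out_of_range:.0%} of planted probes; shrink the effect or the baseline spread")
    target_case = np.clip(target_case, 0.0, 1.0)

    samples = ([f"ctrl_{i+1}" for i in range(cfg.n_ctrl_samples)]
               + [f"case_{i+1}" for i in range(cfg.n_case_samples)])
    conditions = pd.Series(["control"] * cfg.n_ctrl_samples + ["case"] * cfg.n_case_samples,
                           index=samples)

    # per-sample β around the per-condition target, Beta-distributed noise
    eps = 1e-3
    beta_samples = np.empty((n, len(samples)))
    for j, cond in enumerate(conditions):
        mu = np.clip(beta0 if cond == "control" else target_case, eps, 1 - eps)
        beta_samples[:, j] = rng.beta(mu * cfg.beta_noise_conc,
                                      (1 - mu) * cfg.beta_noise_conc)

    # type II design + compression of extreme β
    is_type2 = rng.random(n) < cfg.frac_type2_probes
    s = cfg.type2_compression
    beta_obs = beta_samples.copy()
    beta_obs[is_type2, :] = 0.5 + s * (beta_obs[is_type2, :] - 0.5)

    # intensities: total ~ lognormal around 5000 counts, small multiplicative noise
    total = rng.lognormal(mean=np.log(5000.0), sigma=0.3, size=beta_obs.shape)
    m_noise = rng.lognormal(mean=0.0, sigma=0.01, size=beta_obs.shape)
    u_noise = rng.lognormal(mean=0.0, sigma=0.01, size=beta_obs.shape)
    M = pd.DataFrame(beta_obs * total * m_noise, index=probes, columns=samples)
    U = pd.DataFrame((1 - beta_obs) * total * u_noise, index=probes, columns=samples)

    detection = rng.uniform(0.0, 1e-3, size=beta_obs.shape)
    n_failed = int(round(cfg.frac_failed_probes * n))
    if n_failed:
        # failed probes never overlap the planted signal
        unplanted = np.flatnonzero(~planted)
        failed = rng.choice(unplanted, size=min(n_failed, unplanted.size), replace=False)
        fail_col = rng.integers(len(samples), size=failed.size)
        detection[failed, fail_col] = rng.uniform(0.06, 0.5, size=failed.size)
    detection_p = pd.DataFrame(detection, index=probes, columns=samples)

    probe_table = pd.DataFrame({
        "design_type": np.where(is_type2, "II", "I"),
        "chrom": [f"chr{1 + i % 22}" for i in range(n)],
        "cross_reactive": False,
        "snp_overlap": False,
    }, index=pd.Index(probes, name="probe_id"))
    assignments = pd.DataFrame({
        "probe_id": probes,
        "gene_id": np.where(region == "intergenic", "", gene_assign),
        "region": region,
    })
    ann = ProbeAnnotation(probe_table, assignments)
    truth = GroundTruth(
        hyper_probe_ids={probes[i] for i in hyper_idx},
        hypo_probe_ids={probes[i] for i in hypo_idx},
        repressed_gene_ids=set(repressed),
    )
    truth.conditions = conditions  # carried for convenience of downstream stages
    return M, U, detection_p, ann, truth


def make_expression_dataset(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """TPM-like expression for the 3+6 design with planted down-expression.

    Log-normal baseline per gene; repressed genes are shifted down by
    ``expr_log2fc`` (log2 units) in case samples.  Column order matches the
    methylation samples.
    """
    rng = cfg.rng("expression")
    genes = _gene_ids(cfg.n_genes)
    samples = ([f"ctrl_{i+1}" for i in range(cfg.n_ctrl_samples)]
               + [f"case_{i+1}" for i in range(cfg.n_case_samples)])
    base = rng.normal(5.0, 2.0, size=cfg.n_genes)
    log2 = base[:, None] + rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_genes, len(samples)))
    repressed_mask = np.isin(genes, list(truth.repressed_gene_ids))
    log2[np.ix_(repressed_mask, np.arange(cfg.n_ctrl_samples, len(samples)))] -= cfg.expr_log2fc
    return pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene_id"), columns=samples)


def make_gene_sets(cfg: SynthConfig, truth: GroundTruth) -> GeneSetCollection:
    """Gene-set collection with causal sets enriched for the repressed genes.

    The first ``n_causal_sets`` sets draw ``causal_enrichment`` of their
    members from the repressed genes (decoys draw uniformly from the
    universe); classes alternate TSG-A / OG-I.  Causal set names are recorded
    in ``truth.causal_set_names``.
    """
    rng = cfg.rng("gene_sets")
    genes = np.array(_gene_ids(cfg.n_genes))
    repressed = np.array(sorted(truth.repressed_gene_ids))
    others = genes[~np.isin(genes, repressed)]
    lo, hi = cfg.set_size_range
    sets = []
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        causal = i < cfg.n_causal_sets and repressed.size > 0
        if causal:
            n_plant = min(int(round(cfg.causal_enrichment * size)), repressed.size)
            members = list(rng.choice(repressed, size=n_plant, replace=False))
            members += list(rng.choice(others, size=size - n_plant, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        name = f"SET_{i:03d}"
        sets.append(GeneSet(name, frozenset(members),
                            set_class="TSG-A" if i % 2 == 0 else "OG-I"))
        if causal:
            truth.causal_set_names.add(name)
    return GeneSetCollection(sets)


def make_cohort(cfg: SynthConfig, signature_genes: Sequence[str]):
    """Patient expression matrix + clinical table with a planted hazard.

    Each patient carries a latent standard-normal stress score; signature
    genes load on it with ``cohort_loading`` (negative by default: higher
    latent stress, lower expression, matching the repressed-gene sign
    convention).  Survival times are exponential with log-hazard
    ``hazard_coef`` × latent score; censoring is independent at
    ``censor_rate``.  Returns ``(expr, clinical, latent)`` and stores the
    latent score on the ground truth caller-side via the returned Series.
    """
    if not len(signature_genes):
        raise ValueError("signature_genes must be nonempty")
    if cfg.n_patients < 10:
        raise ValueError(f"n_patients={cfg.n_patients} too small for survival estimation (need ≥10)")
    rng = cfg.rng("cohort")
    genes = _gene_ids(cfg.n_genes)
    unknown = set(signature_genes) - set(genes)
    if unknown:
        raise ValueError(f"signature genes outside the universe: {sorted(unknown)[:5]}")
    patients = [f"pt_{i:04d}" for i in range(cfg.n_patients)]
    latent = pd.Series(rng.normal(size=cfg.n_patients), index=patients, name="latent_score")

    base = rng.normal(5.0, 2.0, size=cfg.n_genes)
    log2 = base[:, None] + rng.normal(0.0, cfg.cohort_noise_sd,
                                      size=(cfg.n_genes, cfg.n_patients))
    sig_mask = np.isin(genes, list(signature_genes))
    log2[sig_mask, :] += cfg.cohort_loading * latent.to_numpy()[None, :]
    expr = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene_id"), columns=patients)

    hazard_scale = cfg.baseline_survival_months * np.exp(-cfg.hazard_coef * latent.to_numpy())
    time = rng.exponential(hazard_scale)
    event = rng.random(cfg.n_patients) >= cfg.censor_rate
    time = np.where(event, time, time * rng.random(cfg.n_patients))
    clinical = pd.DataFrame({
        "time_months": time,
        "event": event.astype(int),
    }, index=pd.Index(patients, name="patient_id"))
    return expr, clinical, latent
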