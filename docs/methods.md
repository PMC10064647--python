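# Methods

This note documents the statistical procedures, the tunable parameters that
matter, what the synthetic data emulate (and do not), and the design choices
made where the procedure was genuinely open.

## Methylation processing

**β and M values.** β = M/(U+M) with no intensity offset by default (an
offset is exposed in the pipeline config). Cells with zero total intensity
are undefined and kept as missing. M-values use the logit2 transform
log2(β/(1−β)) with β clipped to [1e−6, 1−1e−6], so boundary β never produce
infinities; the β↔M round trip is exact to 1e−9 away from the boundary.

**Probe filtering.** A probe is removed when it fails detection (p > 0.05)
in *any* sample — the conservative any-sample policy — or is flagged
cross-reactive or SNP-overlapping, or maps to chrX/chrY. The removal log
records every probe–reason pair.

**Peak-based type II correction.** The two Infinium chemistries differ:
type II probes show compressed extreme β. Per sample, Gaussian kernel
densities (Silverman bandwidth, 1024-point grid) are estimated on the
M-values of type I and type II probes separately; the unmethylated peak is
the highest local maximum at M < 0 and the methylated peak the highest at
M > 0. Type II M-values are rescaled linearly on each side of zero so its
peaks land on the type I peaks; type I values are untouched. When either
design type has fewer than 50 probes, or a sample's distribution yields no
peak on one side (not usably bimodal), that sample passes through unchanged
with a warning rather than being distorted by an unstable fit.

**Differential methylation.** Welch's t-test on M-values (robust to the
unequal group sizes and variances of a 3-vs-6 design), Benjamini–Hochberg
across all retained probes in one batch (not per chromosome or region).
Δβ is the difference of per-condition medians of β. Calls use strict
inequalities: hyper iff Δβ > 0.2 and adjusted p < 0.05; hypo iff
Δβ < −0.2 and adjusted p < 0.05. Δβ exactly 0.2 is therefore *unchanged*.
Probes with zero within-group variance in both groups get p = 1.

## Differential expression

External tables carry a fold-change proxy ("beta", case vs control) and two
FDR-corrected p-values; a gene is significant only when **both** are below
0.05, with direction from the sign of beta. The status column of an input
file is never trusted — it is recomputed on load.

The stand-in test (`standin_de`) runs a pooled-variance t-test on
log2(TPM+1) and fills both q slots with its BH-corrected q, preserving the
two-test AND-rule structurally so a real external table drops in unchanged.
The pooled (rather than per-group) variance is deliberate: with 3 control
replicates a Welch denominator has ≈2 degrees of freedom and its fat tails
cap power regardless of effect size, while log-scale expression noise at
this design is well approximated as homoskedastic. Genes with control mean
TPM < 1 are flagged `low_expressed` (flag only; they are not removed).
The pseudo-count of 1 is the conventional choice.

## Preranked GSEA

Gene-level Δβ for ranking aggregates CpGs assigned to promoter, enhancer or
mixed regions by the **max-|Δβ|** rule (signed value of largest magnitude;
ties resolve to the more positive value): the most affected regulatory CpG
is taken to drive silencing. A mean rule is exposed as a config option.
Rank ties break lexicographically for reproducibility.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: hits increment by |score|^p normalized over hits (p = 1 by default),
misses decrement 1/(N−N_h); the ES is the extremum of largest magnitude
(exact magnitude ties resolve positive). A set covering the entire list is
degenerate and scores 1.0.

The null is gene-tag permutation — random same-size member sets drawn from
the ranked list — which is the appropriate (and only) null for preranked
input; 1000 permutations by default. NES divides the ES by the mean
magnitude of same-sign null ES; the nominal p is one-sided within the
same-sign null pool, floored at 1/(n_perm+1) and set to the floor when the
pool is empty. FDR q follows the pooled positive/negative procedure: the
fraction of all (NES-normalized) null scores at least as extreme divided by
the fraction of observed NES at least as extreme, clipped to [0, 1]. A set
is significant when nominal p and q are both below 0.05.

## Integration

A gene is regulatory-hypermethylated when ≥1 of its promoter, enhancer or
mixed CpGs is called hyper; "mixed" probes (promoter-or-enhancer depending
on cell type) count as regulatory. Gene-body calls are tracked separately
and never confer regulatory status. List 2 (epigenetically repressed) =
down-regulated ∩ regulatory-hypermethylated; list 1 = up-regulated ∩
regulatory-hypomethylated. A gene with both hyper and hypo regulatory calls
is conflicted: excluded from both lists and reported.

Epigenetically repressed pathways are sets significant with NES > 0 on the
methylation ranking **and** significant with NES < 0 on the expression
ranking. The signature is the genes composing these pathways *collectively*
(union), intersected with list 2 — a strict per-pathway intersection of
several sets is near-empty by construction and is available only as a
config option.

## Signature score and refinement

The score is the negated mean of z-scored expression: each signature gene
is standardized across patients (sample sd, ddof = 1; population sd
exposed), the per-patient mean is taken over genes, and the result negated
so that higher score ⇔ lower expression of the (repressed) signature genes.
Scores are exactly mean-zero across patients, affine-invariant per gene,
and anti-monotone in any single expression value. Zero-variance genes have
no defined z and are excluded from the mean (counted, not imputed).

**Refinement sign convention.** Refinement keeps a candidate gene when its
expression correlates with its pathway's module score at R > 0.25 (strict)
and p < 0.05 for at least one of its pathways (Pearson; the raw p is used —
no multiplicity correction, noted in the output). The module score used
here is the pathway *expression* score (the mean z, i.e. the un-negated
form). This is deliberate: under the negated convention, the expression of
any coherently loaded member gene correlates *negatively* with the module
score as a matter of algebra, so a positive-R keep-rule would reject every
true member. Correlating against the expression-sense module score makes
"R > 0.25 kept" select exactly the genes that co-vary with their pathway.
Genes in several pathways are kept if any pathway qualifies.

## Survival

Tertile stratification sorts by (score, patient id); the lowest ⌈n/3⌉
patients are "low" and the highest ⌈n/3⌉ "high", so remainder patients go
to the outer groups — 277 patients split 93/91/93 with equal-size outer
arms. Ties break by patient id. Grouping is invariant to monotone score
transforms. Kaplan–Meier estimation and the two-group log-rank test
(hypergeometric variance, 1 df, no continuity correction) are delegated to
lifelines; with no events anywhere the log-rank is undefined and reported
as (0, p = 1) with a warning. The module is endpoint-agnostic: overall and
disease-specific survival are both just (time, event) pairs.

## Synthetic data

The generator emulates a two-condition methylation array study with 3
control and 6 case replicates plus its downstream cohort. Choices, with
defaults:

- **Baseline β**: a 50/50 two-component Beta mixture with modes ≈0.1 and
  ≈0.9 (concentration 20), matching typical bimodal Infinium marginals.
- **Replicate noise**: per-sample β drawn Beta-distributed around the
  per-condition target with concentration 500 (per-sample β sd ≈ 0.02,
  the order of Infinium technical replicates); log2 expression replicate
  noise sd 0.15.
- **Plants**: 5% of probes hypermethylated (+0.3 β in cases, starting from
  the unmethylated mode), 1% hypomethylated (mirror image). Every
  designated repressed gene (100 of 2000) receives at least one planted
  hyper probe in a promoter or enhancer; remaining plants concentrate in
  regulatory regions. Planted hypo probes never sit on repressed genes —
  the planted truth would otherwise conflict with itself. An effect size
  that would push more than half the planted probes outside [0, 1] is
  rejected.
- **Type II bias**: β′ = 0.5 + s(β − 0.5) with s = 0.8 on a random 85% of
  probes — a one-parameter distortion sufficient to exercise the peak
  correction.
- **Intensities**: U+M log-normal around 5000 counts with ~1% multiplicative
  noise; the β computation is scale-invariant, so the level is cosmetic.
- **Expression**: log-normal baseline (log2 mean ~ N(5, 2)); repressed
  genes shifted down by 1.5 log2 units in cases.
- **Gene sets**: 25 sets of 20–80 genes; 4 "causal" sets draw 80% of their
  members from the repressed genes; classes alternate TSG-A/OG-I.
- **Cohort**: 200 patients; latent stress score ~ N(0,1); signature genes
  load at −0.5 log2 per score unit (negative: repressed) with residual sd
  0.8; survival exponential with log-hazard 0.8 per score unit around 60
  months; independent censoring at 30%.
- **Determinism**: one global seed fans out into four named substreams
  (methylation, expression, gene sets, cohort), so each dataset regenerates
  independently and identically.

What the generator does **not** emulate: probe-level spatial/GC effects,
batch and dye biases beyond the type II compression, count-level RNA-seq
noise (expression is log-normal, not negative-binomial), copy-number or SNP
artifacts, correlated gene–gene co-expression structure beyond the planted
latent factor, and non-proportional hazards. Passing recovery tests on this
generator therefore certifies the pipeline's statistical logic and
plumbing, not its robustness to every artifact of real arrays and cohorts.

## Problem sizes used in the checks

The shipped checks run the chain at 8,000–20,000 probes, 500–2,000 genes,
200–300 patients, 200 permutation replicates for survival calibration, and
1000 GSEA permutations — sizes at which every planted-recovery and
calibration property is comfortably measurable while the whole suite stays
fast on a single core.

## Known limitations

- The peak correction assumes a usably bimodal M-value distribution per
  sample and design type; exotic samples fall back to pass-through.
- The stand-in DE is not a substitute for bootstrap-aware quantification
  inference; it exists so the integration can be exercised end to end and
  swapped for real tables.
- GSEA FDR q-values follow the pooled-null procedure and are not guaranteed
  monotone in NES.
- Exact external study figures that depend on deposited arrays and
  consortium cohorts (total DMC counts, specific signature gene identities,
  cohort correlations and survival p-values) are outside what synthetic
  data can or should reproduce; the pipeline reproduces the procedure and
  its printed arithmetic, and demonstrates recovery on planted truth.
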