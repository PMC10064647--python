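"""Preranked gene-set enrichment analysis.

Implements the weighted Kolmogorov–Smirnov running-sum statistic on a ranked
gene list, a gene-tag permutation null (random same-size member sets drawn
from the ranked list, the standard null for preranked input), sign-aware
normalized enrichment scores, one-sided nominal p-values, and the
positive/negative-pool FDR q-value procedure.

Gene sets carry a class label distinguishing tumor-suppressor-activation
(TSG-A) from oncogene-inhibition (OG-I) signatures; the label is metadata
and does not enter the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "RankedList",
    "make_rank_file",
    "gene_level_delta_beta",
    "enrichment_score",
    "permutation_stats",
    "select_pathways",
]

SET_CLASSES = ("TSG-A", "OG-I")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    set_class: str = "TSG-A"
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.set_class not in SET_CLASSES:
            raise ValueError(f"set class must be one of {SET_CLASSES}, got {self.set_class!r}")


class GeneSetCollection:
    """Named gene sets with TSG-A / OG-I class labels (GMT-backed)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene-set name {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, names: Iterable[str]) -> set[str]:
        """Union of member genes over the given set names."""
        out: set[str] = set()
        for n in names:
            out |= self._sets[n].genes
        return out

    def common_members(self, names: Iterable[str]) -> set[str]:
        """Strict intersection of member genes over the given set names."""
        names = list(names)
        if not names:
            return set()
        out = set(self._sets[names[0]].genes)
        for n in names[1:]:
            out &= self._sets[n].genes
        return out


class RankedList:
    """Genes ordered by descending score; ties broken lexicographically."""

    def __init__(self, scores: Mapping[str, float] | pd.Series):
        s = pd.Series(dict(scores), dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
        if s.empty:
            raise ValueError("cannot rank an empty score table")
        if not s.index.is_unique:
            dup = s.index[s.index.duplicated()].unique()
            raise ValueError(f"duplicate genes in ranking: {list(dup[:5])}")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("non-finite scores in ranking")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        self.scores = s.loc[order]

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def positions(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based rank positions of the members present in the list."""
        member_set = set(members)
        mask = self.scores.index.isin(member_set)
        return np.flatnonzero(mask)


def make_rank_file(scores: Mapping[str, float] | pd.Series) -> RankedList:
    """Build a ranked list (RNK-style) from per-gene scores."""
    return RankedList(scores)


def gene_level_delta_beta(dmc: pd.DataFrame, assignments: pd.DataFrame,
                          regions: Iterable[str] = ("promoter", "enhancer", "mixed"),
                          rule: str = "max_abs") -> pd.Series:
    """Aggregate CpG-level Δβ to one score per gene for ranking.

    Each gene gets the Δβ of its CpGs assigned to the chosen region classes,
    combined by ``rule``:

    - ``max_abs`` (default): the signed Δβ of largest magnitude — the most
      affected regulatory CpG is taken to drive silencing;
    - ``mean``: the mean Δβ over those CpGs.

    Ties in magnitude resolve to the more positive value, then are stable in
    probe order, so results are deterministic.
    """
    if rule not in {"max_abs", "mean"}:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    assign = assignments[assignments["region"].isin(set(regions))]
    assign = assign[assign["gene_id"].fillna("") != ""]
    merged = assign.merge(dmc[["delta_beta"]], left_on="probe_id", right_index=True)
    if merged.empty:
        raise ValueError("no CpG falls in the requested region classes")
    if rule == "mean":
        return merged.groupby("gene_id")["delta_beta"].mean()

    def _max_abs(values: pd.Series) -> float:
        arr = values.to_numpy()
        top = np.abs(arr).max()
        candidates = arr[np.abs(arr) == top]
        return float(candidates.max())

    return merged.groupby("gene_id")["delta_beta"].agg(_max_abs)


def _hit_weights(scores: np.ndarray, positions: np.ndarray, weight_p: float) -> np.ndarray:
    w = np.abs(scores[positions]) ** weight_p
    total = w.sum()
    if total <= 0:  # all hit scores zero -> fall back to equal weights
        return np.full(len(positions), 1.0 / len(positions))
    return w / total


def enrichment_score(ranked: RankedList, members: Iterable[str],
                     weight_p: float = 1.0):
    """Weighted running-sum enrichment score of a gene set on a ranked list.

    Walking down the list, the running sum rises by |score|^weight_p
    (normalized over hits) at each member gene and falls by 1/(N − N_h) at
    each non-member; the ES is the extremum of largest magnitude.  The
    leading edge is the members at or before the extremum (positive ES) or
    after it (negative ES).

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has one
    value per list position (after processing that gene).
    """
    positions = ranked.positions(members)
    n = len(ranked)
    k = len(positions)
    if k == 0:
        raise ValueError("no member of the set appears in the ranked list")
    scores = ranked.scores.to_numpy()
    hit = np.zeros(n)
    hit[positions] = _hit_weights(scores, positions, weight_p)
    if k == n:  # degenerate: every gene is a member, no misses possible
        running = np.cumsum(hit)
        return 1.0, running, list(ranked.genes)
    miss = np.full(n, -1.0 / (n - k))
    miss[positions] = 0.0
    running = np.cumsum(hit + miss)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # exact magnitude ties (possible with unweighted increments) resolve positive
    if running[i_max] >= -running[i_min] - 1e-12:
        es = float(running[i_max])
        leading = [g for g in ranked.genes[: i_max + 1] if g in set(members)]
    else:
        es = float(running[i_min])
        leading = [g for g in ranked.genes[i_min + 1:] if g in set(members)]
    return es, running, leading


def _null_es(scores: np.ndarray, k: int, n_perm: int, weight_p: float,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES from random k-subsets of list positions (gene-tag permutation)."""
    n = len(scores)
    if k >= n:
        return np.ones(n_perm)
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    idx.sort(axis=1)
    w = np.abs(scores) ** weight_p
    hitw = w[idx]
    totals = hitw.sum(axis=1, keepdims=True)
    hitw = np.where(totals > 0, hitw / np.where(totals == 0, 1, totals),
                    1.0 / k)
    cum = np.cumsum(hitw, axis=1)
    j = np.arange(1, k + 1)
    dec = 1.0 / (n - k)
    # running sum just after each hit, and just before each hit
    after = cum - (idx + 1 - j) * dec
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (idx - (j - 1)) * dec
    es_pos = after.max(axis=1)
    es_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


def permutation_stats(ranked: RankedList, collection: GeneSetCollection,
                      n_perm: int = 1000, weight_p: float = 1.0,
                      seed: int | np.random.Generator = 0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """ES, NES, nominal p and FDR q for every set in the collection.

    The null is gene-tag permutation: ``n_perm`` random member sets of the
    same size drawn from the ranked list.  NES divides the ES by the mean
    magnitude of same-sign null scores; nominal p is one-sided within the
    same-sign null pool (floored at 1/(n_perm+1) and set to that floor when
    the pool is empty); FDR q follows the pooled positive/negative procedure:
    the fraction of all null NES at least as extreme, divided by the fraction
    of observed NES at least as extreme, clipped to [0, 1].  ``significant``
    marks sets with nominal p and q both below ``alpha``.  Deterministic
    under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be ≥100, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = ranked.scores.to_numpy()
    n = len(ranked)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    floor = 1.0 / (n_perm + 1)
    for gs in collection:
        positions = ranked.positions(gs.genes)
        k = len(positions)
        if k == 0:
            raise ValueError(f"set {gs.name!r} has no member in the ranked list")
        if len(gs.genes) > n and k < len(gs.genes):
            pass  # members absent from the list are simply ignored
        es, _, leading = enrichment_score(ranked, gs.genes, weight_p)
        null = _null_es(scores, k, n_perm, weight_p, rng)
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan

        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
            p = max(float((pos_null >= es).sum()) / pos_null.size, floor) if pos_null.size else floor
        else:
            nes = -(abs(es) / mean_neg) if np.isfinite(mean_neg) else np.nan
            p = max(float((neg_null <= es).sum()) / neg_null.size, floor) if neg_null.size else floor

        null_nes = np.where(null >= 0,
                            null / (mean_pos if np.isfinite(mean_pos) else np.inf),
                            -(np.abs(null) / (mean_neg if np.isfinite(mean_neg) else np.inf)))
        null_nes_pool.append(null_nes)
        rows.append({"name": gs.name, "set_class": gs.set_class, "size": k,
                     "es": es, "nes": nes, "p_nominal": p,
                     "leading_edge": leading})

    res = pd.DataFrame(rows).set_index("name")
    pool = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()
    q = np.empty(len(res))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            null_frac_den = (pool >= 0).sum()
            null_frac = (pool >= nes).sum() / null_frac_den if null_frac_den else 1.0
            obs_den = (obs >= 0).sum()
            obs_frac = (obs >= nes).sum() / obs_den if obs_den else 1.0
        else:
            null_frac_den = (pool < 0).sum()
            null_frac = (pool <= nes).sum() / null_frac_den if null_frac_den else 1.0
            obs_den = (obs < 0).sum()
            obs_frac = (obs <= nes).sum() / obs_den if obs_den else 1.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    res["fdr_q"] = q
    res["significant"] = (res["p_nominal"] < alpha) & (res["fdr_q"] < alpha)
    return res


def select_pathways(results: pd.DataFrame, direction: str) -> list[str]:
    """Names of significant sets whose NES sign matches ``direction``.

    ``direction`` is "positive" (NES > 0; e.g. hypermethylated pathways on a
    Δβ ranking) or "negative" (NES < 0; e.g. underexpressed pathways on an
    expression ranking).
    """
    if direction not in {"positive", "negative"}:
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    if results.empty:
        return []
    sign_ok = results["nes"] > 0 if direction == "positive" else results["nes"] < 0
    return list(results.index[results["significant"] & sign_ok])
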