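"""Preranked gene-set enrichment with permutation significance.

The weighted Kolmogorov-Smirnov running-sum statistic: walking down a
gene list ranked by a differential-expression metric, the running sum
rises by a hit gene's weighted score fraction and falls by 1/(N - Nh)
at misses; the enrichment score (ES) is the running-sum value of
maximal absolute value, sign preserved. Significance comes from
gene-set permutation (random same-size gene draws) — the natural null
for a preranked list, where phenotype permutation is unavailable:

* NES = ES / mean(|null ES|) over same-sign null draws;
* p = (1 + #{null draws with |ES_null| >= |ES|}) / (1 + n_perm), the
  pseudo-counted two-sided permutation p over all null draws (exactly
  uniform under the null irrespective of any null-ES asymmetry, and
  resolving to 1/(n_perm+1) for a maximally enriched set);
* FDR q by the standard signed pooled-NES procedure: every null ES is
  normalized by its set's same-sign null mean, pooled across sets, and
  q = (null tail fraction at |NES|) / (observed tail fraction), clipped
  to [0, 1].

Cross-contrast discordance: a pathway significantly enriched (q below
the 0.25 threshold) with opposite NES sign in two contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "nes_matrix",
    "discordant_pathways",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class RankedList:
    """Genes with ranking scores, sorted descending, deterministically tie-broken.

    ``ties`` records groups of genes that shared an identical metric and
    were ordered lexicographically.
    """

    genes: tuple
    scores: np.ndarray
    ties: tuple = ()

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate symbols")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (MSigDB GMT-style) with optional descriptions."""

    sets: Mapping
    descriptions: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "sets", {name: frozenset(members) for name, members in self.sets.items()}
        )
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> member genes.

    Duplicate members within a set are deduplicated silently; duplicate
    set names are rejected.
    """
    sets = {}
    descriptions = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def rank_genes(deg: pd.DataFrame, metric: str = "signed_logp") -> RankedList:
    """Rank a DEG table into a preranked list.

    Metrics: ``signed_logp`` (default) = sign(log2FC) * (-log10 p), using
    both effect direction and evidence; ``log2fc`` = the raw fold change.
    p-values must lie in (0, 1] and are floored at 1e-300 before the log.
    Ties are broken by gene symbol (lexicographic) and recorded.
    """
    genes = list(deg.index.astype(str))
    if len(set(genes)) != len(genes):
        raise ValueError("DEG table contains duplicate gene symbols")
    lfc = deg["log2_fold_change"].to_numpy(dtype=float)
    if metric == "signed_logp":
        p = deg["p_value"].to_numpy(dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        scores = np.sign(lfc) * (-np.log10(np.maximum(p, P_FLOOR)))
    elif metric == "log2fc":
        scores = lfc.copy()
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")

    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    sorted_genes = tuple(genes[i] for i in order)
    sorted_scores = np.array([scores[i] for i in order])

    ties = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ties.append(tuple(sorted_genes[i : j + 1]))
        i = j + 1
    return RankedList(genes=sorted_genes, scores=sorted_scores, ties=tuple(ties))


def _es_curve(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float):
    """Running sum and ES for one hit indicator over one ranked list."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    weights = np.abs(scores) ** weight_exponent if weight_exponent != 0 else np.ones(n)
    denom = weights[hit_mask].sum()
    if denom == 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        weights = np.ones(n)
        denom = float(n_hits)
    steps = np.where(hit_mask, weights / denom, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = 1.0
) -> tuple:
    """Weighted-KS enrichment score of one gene set.

    Returns ``(ES, running_sum)``. With ``weight_exponent=0`` the
    statistic reduces to the classical two-sample KS statistic on ranks.
    Requires at least one hit and at least one miss.
    """
    gene_set = set(gene_set)
    hit_mask = np.fromiter((g in gene_set for g in ranked.genes), bool, len(ranked))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == len(ranked):
        raise ValueError("gene set covers the entire ranked list")
    es, running, _ = _es_curve(ranked.scores, hit_mask, weight_exponent)
    return es, running


def _null_es(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """Null ES from random same-size gene draws, vectorized in blocks."""
    n = scores.size
    weights = np.abs(scores) ** weight_exponent if weight_exponent != 0 else np.ones(n)
    out = np.empty(n_perm)
    block = max(1, int(2e7 // n))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # b distinct draws of set_size positions each
        keys = rng.random((b, n))
        pos = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        hit = np.zeros((b, n), dtype=bool)
        np.put_along_axis(hit, pos, True, axis=1)
        w = np.where(hit, weights[None, :], 0.0)
        denom = w.sum(axis=1, keepdims=True)
        fallback = denom[:, 0] == 0
        if fallback.any():
            w[fallback] = hit[fallback].astype(float)
            denom[fallback] = float(set_size)
        steps = np.where(hit, w / denom, -1.0 / (n - set_size))
        running = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        out[done : done + b] = running[np.arange(b), idx]
        done += b
    return out


def _signed_mean(null_es: np.ndarray, sign: float) -> float:
    same = null_es[null_es > 0] if sign >= 0 else -null_es[null_es < 0]
    if same.size == 0:
        same = np.abs(null_es)
    return float(same.mean()) if same.size else np.nan


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    seed: int,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Run preranked GSEA over a gene-set collection.

    Sets are filtered to [min_size, max_size] after intersection with the
    ranked list. Deterministic given the seed: sets are processed in
    sorted name order with a single random stream.

    Returns a DataFrame indexed by set name with columns size, es, nes,
    p, q, leading_edge (number of hits up to the ES extremum).
    """
    genes = ranked.genes
    universe = set(genes)
    surviving = {}
    for name in sorted(sets.sets):
        overlap = sets.sets[name] & universe
        if min_size <= len(overlap) <= max_size and len(overlap) < len(genes):
            surviving[name] = overlap
    if not surviving:
        raise ValueError("no gene set survives the size filter")

    rng = np.random.default_rng(seed)
    scores = ranked.scores
    rows = {}
    null_by_set = {}
    for name, members in surviving.items():
        hit_mask = np.fromiter((g in members for g in genes), bool, len(genes))
        es, running, idx = _es_curve(scores, hit_mask, weight_exponent)
        if es >= 0:
            leading = int(hit_mask[: idx + 1].sum())
        else:
            leading = int(hit_mask[idx:].sum())
        null_es = _null_es(scores, len(members), n_perm, rng, weight_exponent)
        null_by_set[name] = null_es
        n_extreme = int(np.sum(np.abs(null_es) >= abs(es)))
        p = (1 + n_extreme) / (1 + n_perm)
        mean_same = _signed_mean(null_es, np.sign(es) if es != 0 else 1.0)
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        rows[name] = {"size": len(members), "es": es, "nes": nes, "p": p,
                      "leading_edge": leading}

    # pooled signed-null FDR: normalize each set's null ES by that set's
    # same-sign null mean, pool, and compare tail fractions
    pooled = []
    for name, null_es in null_by_set.items():
        pos_mean = _signed_mean(null_es, 1.0)
        neg_mean = _signed_mean(null_es, -1.0)
        nn = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
        pooled.append(nn)
    pooled = np.concatenate(pooled)
    obs_nes = np.array([rows[name]["nes"] for name in rows])
    for name in rows:
        nes = rows[name]["nes"]
        if not np.isfinite(nes):
            rows[name]["q"] = np.nan
            continue
        if nes >= 0:
            null_pool = pooled[pooled >= 0]
            obs_pool = obs_nes[obs_nes >= 0]
            null_tail = np.mean(null_pool >= nes) if null_pool.size else 0.0
            obs_tail = np.mean(obs_pool >= nes)
        else:
            null_pool = pooled[pooled < 0]
            obs_pool = obs_nes[obs_nes < 0]
            null_tail = np.mean(null_pool <= nes) if null_pool.size else 0.0
            obs_tail = np.mean(obs_pool <= nes)
        rows[name]["q"] = float(np.clip(null_tail / obs_tail, 0.0, 1.0))

    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out[["size", "es", "nes", "p", "q", "leading_edge"]]
    out.index.name = "gene_set"
    return out


def nes_matrix(results_by_contrast, fdr_max: float = 0.25) -> pd.DataFrame:
    """Pathway x contrast matrix of significant NES values.

    ``results_by_contrast`` maps contrast name -> GSEA result table (or
    is a sequence of (name, table) pairs, in which case name collisions
    are rejected). NES is retained where q < ``fdr_max``; other cells are
    NaN (not significant); pathways significant nowhere are dropped.
    """
    if isinstance(results_by_contrast, Mapping):
        items = list(results_by_contrast.items())
    else:
        items = list(results_by_contrast)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError(f"contrast name collision: {names}")
    if len(items) < 2:
        raise ValueError("need >= 2 contrasts")
    columns = {}
    for name, table in items:
        sig = table.loc[table["q"] < fdr_max, "nes"]
        columns[name] = sig
    out = pd.DataFrame(columns)
    out = out.dropna(how="all")
    out.index.name = "gene_set"
    if out.empty:
        warnings.warn("no pathway significant in any contrast", stacklevel=2)
    return out


def discordant_pathways(nes: pd.DataFrame, contrast_a: str, contrast_b: str) -> pd.DataFrame:
    """Pathways significantly enriched with opposite sign in two contrasts.

    Sorted by |NES_a - NES_b| descending. Both contrasts must be columns
    of the NES matrix (as produced by :func:`nes_matrix`, where NaN means
    not significant).
    """
    for c in (contrast_a, contrast_b):
        if c not in nes.columns:
            raise ValueError(f"unknown contrast {c!r}; have {list(nes.columns)}")
    a = nes[contrast_a]
    b = nes[contrast_b]
    mask = a.notna() & b.notna() & (np.sign(a) * np.sign(b) < 0)
    out = pd.DataFrame(
        {"nes_a": a[mask], "nes_b": b[mask], "gap": (a[mask] - b[mask]).abs()}
    )
    out = out.sort_values("gap", ascending=False)
    out.attrs["contrasts"] = (contrast_a, contrast_b)
    return out
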