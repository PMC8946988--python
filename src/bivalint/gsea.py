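"""Gene-set enrichment: weighted running-sum enrichment scores and
permutation-normalized NES.

The enrichment score (ES) is the signed maximum deviation of a running sum
that increments by |stat|**p (normalized over set members) at each member
of the set and decrements by 1/(N - n) elsewhere. The null distribution
comes from random same-size gene sets (gene-set permutation, the
appropriate scheme when the experiment has too few samples for phenotype
permutation); NES divides the ES by the mean magnitude of same-signed null
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEResult, _bh
from .io_formats import GeneSetCollection


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a ranking statistic, descending; ties broken by symbol."""

    genes: np.ndarray
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats must align")
        if not np.isfinite(self.stats).all():
            raise ValueError("ranking statistics must be finite")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(de: DEResult, stat: str = "wald") -> RankedList:
    """Rank genes by the Wald statistic or the log2 fold change, descending."""
    if stat not in ("wald", "log2fc"):
        raise ValueError(f"unknown ranking statistic {stat!r}")
    col = "wald_stat" if stat == "wald" else "log2fc"
    values = de.table[col]
    if values.isna().any():
        raise ValueError("NA ranking statistic")
    if de.table.index.duplicated().any():
        raise ValueError("duplicate gene in DE result")
    order = sorted(zip(-values.to_numpy(), de.table.index), key=lambda t: (t[0], t[1]))
    genes = np.array([g for _, g in order])
    stats_sorted = np.array([-v for v, _ in order])
    return RankedList(genes, stats_sorted)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> float:
    """ES from sorted hit positions and their (unnormalized) hit weights.

    The walk's extrema occur immediately after a hit (candidate maximum) or
    immediately before one (candidate minimum), so only hit positions need
    to be visited.
    """
    n = len(positions)
    miss = 1.0 / (n_total - n)
    total = weights.sum()
    if total <= 0:
        cum_hits = np.arange(1, n + 1) / n  # all-zero stats: unweighted hits
    else:
        cum_hits = np.cumsum(weights) / total
    k = np.arange(n)
    after = cum_hits - (positions + 1 - (k + 1)) * miss
    before = np.concatenate([[0.0], cum_hits[:-1]]) - (positions - k) * miss
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked: RankedList,
    gene_set: set[str],
    p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov-like enrichment score with running sum."""
    members = {g.upper() for g in gene_set}
    hit = np.isin(ranked.genes, list(members))
    n = int(hit.sum())
    if n == 0:
        raise ValueError("no gene-set member present in the ranked universe")
    N = len(ranked)
    w = np.abs(ranked.stats) ** p
    if n == N:
        # degenerate all-gene set: pure hit walk, peaks at 1
        total = w.sum()
        running = np.cumsum(w / total) if total > 0 else np.arange(1, N + 1) / N
        return 1.0, running
    increments = np.where(hit, 0.0, -1.0 / (N - n))
    hw = w[hit]
    total = hw.sum()
    if total > 0:
        increments[hit] = hw / total
    else:
        increments[hit] = 1.0 / n
    running = np.cumsum(increments)
    hi = float(running.max())
    lo = float(min(running.min(), 0.0))
    es = hi if hi >= -lo else lo
    return es, running


@dataclass(frozen=True)
class GSEAResult:
    """Per-set ES, NES, empirical p and BH q."""

    table: pd.DataFrame
    n_perm: int


def gsea_nes(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    perm: str = "gene_set",
    seed: int = 0,
    p: float = 1.0,
) -> GSEAResult:
    """ES, permutation-normalized NES and empirical p for every set.

    Null scores come from ``n_perm`` random same-size gene sets; the null is
    shared between sets of equal effective size. NES = ES / mean(|null ES|
    of matching sign); p is the fraction of same-signed null scores at least
    as extreme (with the observed score counted once).
    """
    if perm != "gene_set":
        raise ValueError("only gene-set permutation is supported")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    w = np.abs(ranked.stats) ** p
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}

    null_cache: dict[int, np.ndarray] = {}

    def null_scores(size: int) -> np.ndarray:
        if size not in null_cache:
            scores = np.empty(n_perm)
            for b in range(n_perm):
                pos = np.sort(rng.choice(N, size=size, replace=False))
                scores[b] = _es_from_positions(pos, w[pos], N)
            null_cache[size] = scores
        return null_cache[size]

    rows = []
    for name in collection.names():
        members = collection[name]
        pos = np.sort([gene_pos[g] for g in members if g in gene_pos])
        if len(pos) == 0:
            raise ValueError(f"gene set {name!r} has no member in the ranked universe")
        if len(pos) > N:
            raise ValueError(f"gene set {name!r} larger than the universe")
        if len(pos) == N:
            es = 1.0
        else:
            es = _es_from_positions(pos, w[pos], N)
        null = null_scores(len(pos))
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, pval = float("nan"), 1.0
        else:
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else float("nan")
            pval = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        rows.append((name, len(pos), es, nes, pval))
    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "pvalue"]).set_index("set")
    table["qvalue"] = _bh(table["pvalue"].to_numpy())
    return GSEAResult(table, n_perm)
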