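"""Promoter chromatin states and association statistics.

Promoters are symmetric windows on the primary TSS (3 kb total by default).
A promoter is "bivalent" when replicate-consensus peaks of both the
activating H3K4me3 mark and the repressive H3K27me3 mark overlap it; such
promoters are repressed by PRC2 yet poised for activation. Association
tests are hypergeometric (set overlap), Fisher exact (2x2 flags) and
Wilcoxon rank-sum (expression by state), plus a cross-sample test relating
promoter H3K27me3 to expression of one target gene across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .io_formats import GeneAnnotation, PeakSet, make_peakset

STATES = ("bivalent", "K4-only", "K27-only", "neither")


# ---------------------------------------------------------------------------
# Promoters and interval machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterTable:
    """Per-gene promoter window [tss - w/2, tss + w/2), clipped at zero.

    ``table``: index gene; columns chrom, start, end.
    """

    table: pd.DataFrame
    width: int

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def make_promoters(annotation: GeneAnnotation, width: int = 3000) -> PromoterTable:
    """Strand-invariant symmetric promoter windows around the TSS."""
    if width <= 0 or width % 2 != 0:
        raise ValueError("promoter width must be a positive even integer")
    half = width // 2
    t = annotation.table
    start = np.maximum(t["tss"].to_numpy() - half, 0)
    end = t["tss"].to_numpy() + half
    return PromoterTable(
        pd.DataFrame({"chrom": t["chrom"].values, "start": start, "end": end}, index=t.index),
        width,
    )


def _peaks_to_pr(df: pd.DataFrame, extra: dict | None = None) -> pr.PyRanges:
    data = {"Chromosome": df["chrom"].values, "Start": df["start"].values, "End": df["end"].values}
    if extra:
        data.update(extra)
    return pr.PyRanges(pd.DataFrame(data))


def consensus_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Replicate-consensus peaks: union spans of overlapping rep1/rep2 pairs.

    Each rep1 peak overlapping (>= 1 bp) any rep2 peak contributes the union
    interval over itself and all rep2 peaks it touches; overlapping results
    are merged. The consensus signal is the sum of all member-peak signals
    overlapping the merged interval (each member counted once).
    """
    if rep1.mark != rep2.mark:
        raise ValueError(f"mark mismatch: {rep1.mark!r} vs {rep2.mark!r}")
    if len(rep1) == 0 or len(rep2) == 0:
        return make_peakset(rep1.mark, 0, [], [], [])
    a = _peaks_to_pr(rep1.intervals, {"idx": np.arange(len(rep1))})
    b = _peaks_to_pr(rep2.intervals)
    joined = a.join(b).df
    if joined.empty:
        return make_peakset(rep1.mark, 0, [], [], [])
    # union span per rep1 anchor over all its rep2 partners
    spans = (
        joined.assign(
            u_start=np.minimum(joined["Start"], joined["Start_b"]),
            u_end=np.maximum(joined["End"], joined["End_b"]),
        )
        .groupby("idx")
        .agg(Chromosome=("Chromosome", "first"), Start=("u_start", "min"), End=("u_end", "max"))
        .reset_index(drop=True)
    )
    merged = pr.PyRanges(spans).merge().df

    # recompute signal: sum of distinct rep1 + rep2 peaks overlapping each region
    out = merged.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    out["chrom"] = out["chrom"].astype(str)
    region = pr.PyRanges(merged.assign(rid=np.arange(len(merged))))
    signal = np.zeros(len(merged))
    for rep in (rep1, rep2):
        hits = region.join(_peaks_to_pr(rep.intervals, {"sig": rep.intervals["signal"].values})).df
        if not hits.empty:
            per_region = hits.groupby("rid")["sig"].sum()
            signal[per_region.index.to_numpy()] += per_region.to_numpy()
    out["signal"] = signal
    return make_peakset(rep1.mark, 0, out["chrom"], out["start"], out["end"], out["signal"])


def intersect_peaksets(a: PeakSet, b: PeakSet, mark: str | None = None) -> PeakSet:
    """Coordinate intersection of two peak sets (e.g. H3K27ac with ATAC).

    The intersected interval keeps the signal of ``a`` (the quantitative
    mark); overlapping outputs are merged with summed signal.
    """
    if len(a) == 0 or len(b) == 0:
        return make_peakset(mark or a.mark, 0, [], [], [])
    ga = _peaks_to_pr(a.intervals, {"sig": a.intervals["signal"].values})
    gb = _peaks_to_pr(b.intervals)
    joined = ga.join(gb).df
    if joined.empty:
        return make_peakset(mark or a.mark, 0, [], [], [])
    starts = np.maximum(joined["Start"], joined["Start_b"])
    ends = np.minimum(joined["End"], joined["End_b"])
    df = pd.DataFrame(
        {"Chromosome": joined["Chromosome"], "Start": starts, "End": ends, "sig": joined["sig"]}
    )
    merged = pr.PyRanges(df[["Chromosome", "Start", "End"]]).merge().df
    region = pr.PyRanges(merged.assign(rid=np.arange(len(merged))))
    hits = region.join(pr.PyRanges(df)).df
    signal = np.zeros(len(merged))
    if not hits.empty:
        per_region = hits.drop_duplicates(["rid", "Start_b", "End_b", "sig"]).groupby("rid")["sig"].sum()
        signal[per_region.index.to_numpy()] += per_region.to_numpy()
    return make_peakset(
        mark or a.mark, 0,
        merged["Chromosome"].astype(str), merged["Start"], merged["End"], signal,
    )


def flag_promoter_overlap(promoters: PromoterTable, peaks: PeakSet) -> pd.Series:
    """True per gene iff >= 1 bp of any peak intersects the promoter window."""
    flags = pd.Series(False, index=promoters.genes, name=peaks.mark)
    if len(peaks) == 0:
        return flags
    prom = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": promoters.table["chrom"].values,
                "Start": promoters.table["start"].values,
                "End": promoters.table["end"].values,
                "gene": promoters.genes.values,
            }
        )
    )
    hit = prom.overlap(_peaks_to_pr(peaks.intervals)).df
    if not hit.empty:
        flags.loc[hit["gene"].values] = True
    return flags


# ---------------------------------------------------------------------------
# Chromatin state classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatinStateTable:
    """Per-gene promoter flags and state in {bivalent, K4-only, K27-only, neither}."""

    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def genes_in_state(self, state: str) -> pd.Index:
        return self.table.index[self.table["state"] == state]


def classify_states(
    k4: pd.Series,
    k27: pd.Series,
    expressed_universe: set[str] | None = None,
    arid1a: pd.Series | None = None,
) -> tuple[ChromatinStateTable, dict[str, float]]:
    """Partition genes into bivalent / K4-only / K27-only / neither.

    Restricted to ``expressed_universe`` when given. The summary reports the
    state counts and the bivalent fraction among H3K4me3-marked promoters.
    """
    if not k4.index.equals(k27.index):
        raise ValueError("flag vectors cover different universes")
    genes = k4.index
    if expressed_universe is not None:
        keep = genes.isin({g.upper() for g in expressed_universe})
        genes = genes[keep]
        k4, k27 = k4[keep], k27[keep]
        if arid1a is not None:
            arid1a = arid1a[keep]
    state = pd.Series("neither", index=genes)
    state[k4 & k27] = "bivalent"
    state[k4 & ~k27] = "K4-only"
    state[~k4 & k27] = "K27-only"
    table = pd.DataFrame({"has_k4": k4, "has_k27": k27, "state": state}, index=genes)
    if arid1a is not None:
        table["arid1a_bound"] = arid1a
    counts = {s: int((state == s).sum()) for s in STATES}
    n_k4 = counts["bivalent"] + counts["K4-only"]
    summary = {
        **counts,
        "universe": len(genes),
        "bivalent_fraction_of_k4": counts["bivalent"] / n_k4 if n_k4 else float("nan"),
    }
    return ChromatinStateTable(table), summary


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentStat:
    overlap: int
    expected: float
    p_hyper: float
    odds_ratio: float
    p_fisher: float
    degenerate: bool = False  # Haldane correction applied to the odds ratio


def _table_stats(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher p and odds ratio with Haldane fallback for zero cells."""
    _, p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    degenerate = 0 in (a, b, c, d)
    if degenerate:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a2 * d2) / (b2 * c2)
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p_fisher), degenerate


def hypergeometric_enrichment(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> EnrichmentStat:
    """Upper-tail hypergeometric overlap test of two gene sets in a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    M, nA, nB = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p_hyper = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    expected = nA * nB / M if M else float("nan")
    a = k
    b = nA - k
    c = nB - k
    d = M - nA - nB + k
    odds, p_fisher, degen = _table_stats(a, b, c, d)
    return EnrichmentStat(k, expected, p_hyper, odds, p_fisher, degen)


def fisher_association(flag_x: pd.Series | np.ndarray, flag_y: pd.Series | np.ndarray) -> EnrichmentStat:
    """Two-sided Fisher exact test of association between two boolean flags."""
    x = np.asarray(flag_x, dtype=bool)
    y = np.asarray(flag_y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("flags must be 1-D and equal length")
    if len(x) == 0:
        raise ValueError("empty flag vectors")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    odds, p_fisher, degen = _table_stats(a, b, c, d)
    M, nA, nB = len(x), a + b, a + c
    p_hyper = float(stats.hypergeom.sf(a - 1, M, nA, nB))
    expected = nA * nB / M
    return EnrichmentStat(a, expected, p_hyper, odds, p_fisher, degen)


def expression_by_state(
    expression: pd.Series,
    states: ChromatinStateTable,
    groups: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of expression between promoter states.

    Groups with fewer than 3 genes yield p = NaN with a warning.
    """
    if not set(states.genes) <= set(expression.index):
        raise ValueError("expression does not cover the state universe")
    if groups is None:
        groups = [
            ("K4-only", "bivalent"), ("bivalent", "K27-only"), ("K4-only", "K27-only"),
        ]
    rows = []
    for g1, g2 in groups:
        x = expression[states.genes_in_state(g1)].to_numpy()
        y = expression[states.genes_in_state(g2)].to_numpy()
        med1 = float(np.median(x)) if len(x) else float("nan")
        med2 = float(np.median(y)) if len(y) else float("nan")
        if len(x) < 3 or len(y) < 3:
            warnings.warn(f"group {g1 if len(x) < 3 else g2!r} has < 3 genes; p set to NaN")
            stat, p = float("nan"), float("nan")
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((g1, g2, len(x), len(y), med1, med2, stat, p))
    return pd.DataFrame(
        rows,
        columns=["group1", "group2", "n1", "n2", "median1", "median2", "statistic", "pvalue"],
    )


# ---------------------------------------------------------------------------
# Cross-sample promoter mark vs expression (Roadmap-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkExpressionComparison:
    marked: np.ndarray         # boolean per sample
    mean_marked: float
    mean_unmarked: float
    ci_marked: tuple[float, float]
    ci_unmarked: tuple[float, float]
    statistic: float
    pvalue: float


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, (float("nan"), float("nan"))
    half = stats.t.ppf(0.5 + level / 2, len(x) - 1) * np.std(x, ddof=1) / np.sqrt(len(x))
    return m, (m - half, m + half)


def promoter_mark_vs_expression(
    expression: np.ndarray,
    peaksets: list[PeakSet],
    target_tss: int,
    chrom: str,
    window: int = 6000,
) -> MarkExpressionComparison:
    """Binarize samples by any peak within ``window``/2 of the target TSS and
    compare expression of marked vs unmarked samples (Wilcoxon two-sided,
    group means with 95 percent CI).

    The default 6 kb total window means "within 3 kb of the TSS".
    """
    expression = np.asarray(expression, dtype=float)
    if len(expression) != len(peaksets):
        raise ValueError("one expression value per peak set required")
    half = window // 2
    lo, hi = max(0, target_tss - half), target_tss + half
    marked = np.zeros(len(peaksets), dtype=bool)
    for i, ps in enumerate(peaksets):
        df = ps.intervals
        sel = (df["chrom"] == chrom) & (df["start"] < hi) & (df["end"] > lo)
        marked[i] = bool(sel.any())
    for name, group in (("marked", marked), ("unmarked", ~marked)):
        if group.sum() == 0:
            raise ValueError(f"group {name!r} is empty after binarization")
        if group.sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    x, y = expression[marked], expression[~marked]
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    mean_m, ci_m = _mean_ci(x)
    mean_u, ci_u = _mean_ci(y)
    return MarkExpressionComparison(
        marked, mean_m, mean_u, ci_m, ci_u, float(res.statistic), float(res.pvalue)
    )
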