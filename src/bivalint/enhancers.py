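"""ROSE-style super-enhancer stitching, ranking, and gene association.

Active enhancer peaks (H3K27ac intersected with accessibility) are stitched
into regions when closer than a stitching distance (12.5 kb by default),
ranked by total signal, and split into typical vs super-enhancers at the
hockey-stick point of the scaled rank-signal curve (where the slope of the
curve passes 1). Genes are associated to super-enhancers by promoter
containment, 50 kb proximity, or a curated enhancer-gene link table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pyranges as pr

from .chromstate import EnrichmentStat, PromoterTable, hypergeometric_enrichment
from .io_formats import EnhancerGeneLinks, PeakSet

ASSOCIATION_MODES = ("inside", "within50kb", "linked")


def stitch(
    peaks: PeakSet,
    stitch_dist: int = 12_500,
    tss_exclusion: PromoterTable | None = None,
) -> pd.DataFrame:
    """Stitch peaks within ``stitch_dist`` of each other into regions.

    Peaks fully inside a TSS-exclusion window are removed before stitching.
    Returns a DataFrame (chrom, start, end, total_signal, n_peaks, rank,
    is_super) ranked by total signal (rank 1 = strongest); is_super is all
    False until :func:`call_super`.
    """
    if stitch_dist < 0:
        raise ValueError("stitch_dist must be non-negative")
    df = peaks.intervals.copy()
    if tss_exclusion is not None and len(df):
        excl = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": tss_exclusion.table["chrom"].values,
                    "Start": tss_exclusion.table["start"].values,
                    "End": tss_exclusion.table["end"].values,
                }
            )
        )
        g = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": df["chrom"].values,
                    "Start": df["start"].values,
                    "End": df["end"].values,
                    "pid": np.arange(len(df)),
                }
            )
        )
        joined = g.join(excl).df
        if not joined.empty:
            contained = joined[(joined["Start"] >= joined["Start_b"]) & (joined["End"] <= joined["End_b"])]
            df = df.drop(df.index[contained["pid"].unique()])
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cur_start = cur_end = None
        cur_signal = 0.0
        cur_n = 0
        for row in sub.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_signal, cur_n = row.start, row.end, row.signal, 1
            elif row.start - cur_end <= stitch_dist:
                cur_end = max(cur_end, row.end)
                cur_signal += row.signal
                cur_n += 1
            else:
                rows.append((chrom, cur_start, cur_end, cur_signal, cur_n))
                cur_start, cur_end, cur_signal, cur_n = row.start, row.end, row.signal, 1
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, cur_signal, cur_n))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "total_signal", "n_peaks"])
    # rank 1 = highest signal; ties broken by coordinates for determinism
    out = out.sort_values(
        ["total_signal", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["is_super"] = False
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_super(regions: pd.DataFrame, method: str = "tangent") -> pd.DataFrame:
    """Mark super-enhancers above the hockey-stick cutoff.

    Regions are sorted ascending by signal and both axes scaled to [0, 1];
    the cutoff sits at the first point where the curve's slope exceeds 1
    (rising faster than the diagonal), and every region with scaled signal
    strictly above the cutoff level is a super-enhancer. A pure linear ramp
    has no unit-slope crossing and yields no super-enhancers.
    """
    if method != "tangent":
        raise ValueError(f"unknown method {method!r}")
    if len(regions) < 3:
        raise ValueError("need >= 3 stitched regions to call super-enhancers")
    out = regions.copy()
    sig = out["total_signal"].to_numpy(dtype=float)
    if np.allclose(sig, sig[0]):
        warnings.warn("all stitched regions have equal signal; no super-enhancers called")
        out["is_super"] = False
        return out
    # ascending by signal, coordinate tie-break
    order = np.lexsort((out["start"].to_numpy(), out["chrom"].to_numpy(), sig))
    y = (sig[order] - sig.min()) / (sig.max() - sig.min())
    n = len(sig)
    x = np.arange(n) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0 + 1e-9)  # tolerance: an exact ramp is not a crossing
    is_super = np.zeros(n, dtype=bool)
    if len(above):
        cutoff = y[above.min()]  # level of the curve entering the steep segment
        is_super[order] = y > cutoff
    out["is_super"] = is_super
    return out


def associate_genes(
    supers: pd.DataFrame,
    promoters: PromoterTable,
    links: EnhancerGeneLinks | None = None,
    mode: str = "within50kb",
    link_min_score: float = 1.0,
) -> set[str]:
    """Genes associated with super-enhancers.

    inside: promoter overlaps a super-enhancer by >= 1 bp. within50kb:
    promoter-to-region gap <= 50,000 bp (overlap counts as gap 0). linked:
    genes whose link rows (score strictly above ``link_min_score``) point at
    an enhancer interval overlapping a super-enhancer.
    """
    if mode not in ASSOCIATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; one of {ASSOCIATION_MODES}")
    se = supers[supers["is_super"]]
    if se.empty:
        return set()
    if mode == "linked":
        if links is None:
            raise ValueError("mode='linked' requires an enhancer-gene link table")
        lt = links.table[links.table["score"] > link_min_score]
        if lt.empty:
            return set()
        enh = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": lt["chrom"].values,
                    "Start": lt["start"].values,
                    "End": lt["end"].values,
                    "gene": lt["gene"].values,
                }
            )
        )
        se_pr = pr.PyRanges(
            pd.DataFrame(
                {"Chromosome": se["chrom"].values, "Start": se["start"].values, "End": se["end"].values}
            )
        )
        hit = enh.overlap(se_pr).df
        return set() if hit.empty else set(hit["gene"])

    max_gap = 0 if mode == "inside" else 50_000
    genes: set[str] = set()
    prom = promoters.table
    for chrom, se_sub in se.groupby("chrom"):
        p_sub = prom[prom["chrom"] == chrom]
        if p_sub.empty:
            continue
        s_starts = se_sub["start"].to_numpy()
        s_ends = se_sub["end"].to_numpy()
        for gene, row in p_sub.iterrows():
            gap = np.maximum(
                0, np.maximum(s_starts - row["end"], row["start"] - s_ends)
            )
            overlap = (s_starts < row["end"]) & (s_ends > row["start"])
            if mode == "inside":
                if overlap.any():
                    genes.add(gene)
            elif (overlap | (gap <= max_gap)).any():
                genes.add(gene)
    return genes


def se_gene_enrichment(
    de_genes: set[str],
    se_genes: set[str],
    active_universe: set[str],
) -> EnrichmentStat:
    """Hypergeometric enrichment of DE genes among super-enhancer genes."""
    return hypergeometric_enrichment(set(de_genes), set(se_genes), set(active_universe))
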