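"""Config-driven orchestration of the full analysis on a synthetic fixture.

``run_all`` simulates a planted-truth dataset, writes the external-format
inputs, runs every stage (differential expression, joint classification,
dependent induction, chromatin states, enrichment statistics,
super-enhancer association, gene-set enrichment, cross-sample comparison,
the printed-table overlap) and emits TSV reports. Every table carries a
commented header with the resolved config hash and is bit-identical across
reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromstate, diffexpr, enhancers, gsea, regclass, synthetic_data
from .io_formats import (
    write_counts, write_gmt, write_links, write_peaks_bed, write_annotation,
)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a full synthetic run."""

    outdir: str
    seed: int = 1
    n_genes: int = 2000
    n_reps: int = 3
    alpha: float = 1e-4
    promoter_width: int = 3000
    roadmap_window: int = 6000
    stitch_dist: int = 12_500
    n_perm: int = 1000
    decoy_fraction: float = 0.1
    panel_samples: int = 56
    panel_marked: int = 20
    panel_ratio: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig(**data)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index_label: str | None = "gene") -> None:
    with open(path, "w") as fh:
        fh.write(f"# bivalint config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label,
                  float_format="%.6g", lineterminator="\n")


def table2_overlap(list_a: list[str], list_b: list[str]) -> dict:
    """Overlap report for two printed gene lists (uppercased, deduplicated)."""
    a = {g.strip().upper() for g in list_a if g.strip()}
    b = {g.strip().upper() for g in list_b if g.strip()}
    inter = sorted(a & b)
    return {"n_a": len(a), "n_b": len(b), "n_overlap": len(inter), "overlap": inter}


def load_table2_lists() -> tuple[list[str], list[str]]:
    """The packaged printed lists of bivalent-promoter genes regulated by E2
    (n=53) and by ARID1A knockdown (n=36)."""
    pkg = importlib.resources.files("bivalint.data")
    e2 = pkg.joinpath("table2_bivalent_e2.txt").read_text().split()
    kd = pkg.joinpath("table2_bivalent_siarid1a.txt").read_text().split()
    return e2, kd


def run_all(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated fixture; returns a result bundle.

    Writes de_<contrast>.tsv (5 tables), classes.tsv, dependent_induction.txt,
    chromatin_states.tsv, enrichment_stats.tsv, se_genes_<mode>.txt, gsea.tsv,
    roadmap.tsv, table2_overlap.tsv and run.log under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    log_lines = [f"bivalint run-all config={config.digest()} seed={config.seed}"]

    # --- simulate and write the external-format inputs -------------------
    truth, ann = synthetic_data.generate_truth(config.n_genes, seed=config.seed)
    expt = synthetic_data.generate_counts(truth, n_reps=config.n_reps, seed=config.seed + 1)
    peaks = synthetic_data.generate_peaks(
        truth, ann, seed=config.seed + 2, decoy_fraction=config.decoy_fraction
    )
    links = synthetic_data.generate_links(truth, ann, seed=config.seed + 3)
    collection = synthetic_data.planted_gene_sets(truth)

    write_annotation(ann, inputs / "annotation.tsv")
    write_counts(expt, inputs / "counts.tsv", inputs / "design.tsv")
    for mark, reps in peaks.items():
        for ps in reps:
            write_peaks_bed(ps, inputs / f"{mark}_rep{ps.replicate}.bed")
    write_links(links, inputs / "enhancer_links.tsv")
    write_gmt(collection, inputs / "planted_sets.gmt")
    log_lines.append(f"simulated {len(truth)} genes, truth digest {synthetic_data.truth_digest(truth)}")

    # --- differential expression -----------------------------------------
    filtered = diffexpr.filter_low_counts(expt)
    fit = diffexpr.FactorialFit(filtered)
    de = {name: fit.contrast(name, alpha=config.alpha) for name in diffexpr.CONTRASTS}
    for name, res in de.items():
        _write_table(res.table, out / f"de_{name.replace('+', '')}.tsv", config)
    log_lines.append(
        f"filtered to {filtered.counts.shape[0]} genes; "
        + "; ".join(f"{n}: {len(r.significant(config.alpha))} DE" for n, r in de.items())
    )

    # --- joint classes, dependent induction ------------------------------
    classes, summary = regclass.classify_joint(de["e2_vs_ctrl"], de["kd_vs_ctrl"], config.alpha)
    _write_table(classes.table, out / "classes.tsv", config)
    dep = regclass.dependent_induction_genes(
        de["e2_vs_ctrl"], de["kd+e2_vs_kd"], de["interaction"], alpha=config.alpha
    )
    (out / "dependent_induction.txt").write_text("\n".join(dep) + "\n")
    groups = regclass.four_group_segregation(classes)
    log_lines.append(
        f"doubly significant: {summary['n_doubly_significant']} "
        f"(coop {summary['cooperative_fraction']:.3f} / antag {summary['antagonistic_fraction']:.3f}); "
        f"dependent induction: {len(dep)} genes; "
        f"4-group sizes: {[len(v) for v in groups.values()]}"
    )

    # --- promoter chromatin states ----------------------------------------
    promoters = chromstate.make_promoters(ann, config.promoter_width)
    consensus = {m: chromstate.consensus_peaks(*peaks[m]) for m in ("H3K4me3", "H3K27me3", "ARID1A")}
    k4 = chromstate.flag_promoter_overlap(promoters, consensus["H3K4me3"])
    k27 = chromstate.flag_promoter_overlap(promoters, consensus["H3K27me3"])
    bound_flags = chromstate.flag_promoter_overlap(promoters, consensus["ARID1A"])
    expressed = set(filtered.genes)
    states, state_summary = chromstate.classify_states(k4, k27, expressed, arid1a=bound_flags)
    _write_table(states.table, out / "chromatin_states.tsv", config)
    log_lines.append(
        "chromatin states: "
        + ", ".join(f"{s}={state_summary[s]}" for s in chromstate.STATES)
        + f"; bivalent fraction of K4 promoters {state_summary['bivalent_fraction_of_k4']:.4f}"
    )

    # --- association statistics -------------------------------------------
    universe = set(states.genes)
    bivalent = set(states.genes_in_state("bivalent"))
    e2_sig = set(de["e2_vs_ctrl"].significant(config.alpha)) & universe
    kd_sig = set(de["kd_vs_ctrl"].significant(config.alpha)) & universe
    stat_rows = []
    for label, A, B in (
        ("bivalent_vs_e2_de", bivalent, e2_sig),
        ("bivalent_vs_kd_de", bivalent, kd_sig),
        ("e2_de_vs_kd_de", e2_sig, kd_sig),
    ):
        st = chromstate.hypergeometric_enrichment(A, B, universe)
        stat_rows.append((label, len(A), len(B), st.overlap, st.expected, st.p_hyper,
                          st.odds_ratio, st.p_fisher))
    fisher = chromstate.fisher_association(
        states.table["state"] == "bivalent", states.table["arid1a_bound"]
    )
    stat_rows.append(("bivalent_vs_arid1a_bound", int((states.table['state'] == 'bivalent').sum()),
                      int(states.table["arid1a_bound"].sum()), fisher.overlap, fisher.expected,
                      fisher.p_hyper, fisher.odds_ratio, fisher.p_fisher))
    enrich_df = pd.DataFrame(
        stat_rows,
        columns=["comparison", "n_a", "n_b", "overlap", "expected", "p_hyper", "odds_ratio", "p_fisher"],
    ).set_index("comparison")
    _write_table(enrich_df, out / "enrichment_stats.tsv", config, index_label="comparison")

    bound_genes = set(states.genes[states.table["arid1a_bound"]])
    regions, central = regclass.intersect_de_with_binding(
        de["e2_vs_ctrl"], de["kd_vs_ctrl"], bound_genes, config.alpha
    )
    log_lines.append(f"triple intersection (E2 DE, KD DE, bound): {regions['e2_kd_bound']} genes")

    # --- super-enhancers ----------------------------------------------------
    k27ac = chromstate.consensus_peaks(*peaks["H3K27ac"])
    atac = chromstate.consensus_peaks(*peaks["ATAC"])
    active = chromstate.intersect_peaksets(k27ac, atac, mark="H3K27ac_ATAC")
    regions_df = enhancers.stitch(active, config.stitch_dist)
    called = enhancers.call_super(regions_df)
    _write_table(called, out / "superenhancers.tsv", config, index_label=None)
    de_any = e2_sig | kd_sig
    se_stats = []
    for mode in enhancers.ASSOCIATION_MODES:
        se_genes = enhancers.associate_genes(
            called, promoters, links=links, mode=mode
        ) & universe
        (out / f"se_genes_{mode}.txt").write_text("\n".join(sorted(se_genes)) + "\n")
        st = enhancers.se_gene_enrichment(de_any, se_genes, universe)
        se_stats.append((mode, len(se_genes), st.overlap, st.expected, st.p_hyper))
    se_df = pd.DataFrame(se_stats, columns=["mode", "n_se_genes", "overlap", "expected", "p_hyper"]).set_index("mode")
    _write_table(se_df, out / "se_enrichment.tsv", config, index_label="mode")
    log_lines.append(
        f"super-enhancers: {int(called['is_super'].sum())} of {len(called)} stitched regions"
    )

    # --- GSEA ---------------------------------------------------------------
    ranked = gsea.rank_genes(de["e2_vs_ctrl"], stat="wald")
    gsea_res = gsea.gsea_nes(ranked, collection, n_perm=config.n_perm, seed=config.seed + 4)
    _write_table(gsea_res.table, out / "gsea.tsv", config, index_label="set")

    # --- cross-sample panel --------------------------------------------------
    expr, panel = synthetic_data.generate_crosssample_panel(
        config.panel_samples, config.panel_marked, config.panel_ratio, seed=config.seed + 5
    )
    cmp_res = chromstate.promoter_mark_vs_expression(
        expr, panel, target_tss=500_000, chrom="chrP", window=config.roadmap_window
    )
    roadmap_df = pd.DataFrame(
        {
            "group": ["marked", "unmarked"],
            "n": [int(cmp_res.marked.sum()), int((~cmp_res.marked).sum())],
            "mean": [cmp_res.mean_marked, cmp_res.mean_unmarked],
            "ci_low": [cmp_res.ci_marked[0], cmp_res.ci_unmarked[0]],
            "ci_high": [cmp_res.ci_marked[1], cmp_res.ci_unmarked[1]],
            "pvalue": [cmp_res.pvalue, cmp_res.pvalue],
        }
    ).set_index("group")
    _write_table(roadmap_df, out / "roadmap.tsv", config, index_label="group")
    log_lines.append(
        f"cross-sample test: marked mean {cmp_res.mean_marked:.2f} vs "
        f"unmarked {cmp_res.mean_unmarked:.2f}, p={cmp_res.pvalue:.3g}"
    )

    # --- printed-table overlap ------------------------------------------------
    e2_list, kd_list = load_table2_lists()
    t2 = table2_overlap(e2_list, kd_list)
    t2_df = pd.DataFrame(
        {"n_e2": [t2["n_a"]], "n_kd": [t2["n_b"]], "n_overlap": [t2["n_overlap"]],
         "overlap": [",".join(t2["overlap"])]}
    )
    _write_table(t2_df, out / "table2_overlap.tsv", config, index_label=None)
    log_lines.append(
        f"printed bivalent lists: {t2['n_a']} x {t2['n_b']}, overlap {t2['n_overlap']}"
    )

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "de": de,
        "classes": classes,
        "class_summary": summary,
        "dependent_induction": dep,
        "states": states,
        "state_summary": state_summary,
        "euler_regions": regions,
        "central_intersection": central,
        "superenhancers": called,
        "gsea": gsea_res,
        "roadmap": cmp_res,
        "table2": t2,
        "truth": truth,
    }
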