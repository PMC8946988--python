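"""Synthetic fixtures with planted ground truth.

Every downstream stage (differential expression, co-regulation classes,
promoter chromatin states, super-enhancer association, gene-set enrichment,
the cross-sample promoter-mark test) is exercised against data generated
here, where the true per-gene effect class, chromatin state and binding
status are known.

The defaults emulate a desk-scale version of a 2x2 estrogen (E2) x
ARID1A-knockdown factorial RNA-seq experiment with three replicates per
condition, plus replicated ChIP-seq-style peak sets for H3K4me3, H3K27me3,
ARID1A, H3K27ac and ATAC.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CountExperiment,
    EnhancerGeneLinks,
    GeneAnnotation,
    GeneSetCollection,
    PeakSet,
    make_collection,
    make_peakset,
)

EFFECT_CLASSES = (
    "null",
    "coop-up",       # E2 up, knockdown down (cooperative, E2-activated)
    "coop-down",     # E2 down, knockdown up
    "antag-up",      # both up
    "antag-down",    # both down
    "dependent-induction",  # E2-induced, attenuated by knockdown (negative interaction)
)

CHROMATIN_STATES = ("bivalent", "K4-only", "K27-only", "neither")
SE_MODES = ("inside", "within50kb", "linked", "none")

# Genes are laid on a deterministic TSS grid so that enhancer clusters placed
# relative to one gene can never stray into a neighbour's 50 kb halo.
TSS_SPACING = 200_000
PROMOTER_HALF = 1_500  # half of the 3 kb promoter window

DEFAULT_CLASS_FRACTIONS = {
    "coop-up": 0.06,
    "coop-down": 0.05,
    "antag-up": 0.03,
    "antag-down": 0.03,
    "dependent-induction": 0.03,
}
DEFAULT_STATE_FRACTIONS = {"bivalent": 0.05, "K4-only": 0.60, "K27-only": 0.07}
DEFAULT_SE_FRACTIONS = {"inside": 0.02, "within50kb": 0.03, "linked": 0.04}
DEFAULT_ARID1A_FRACTION = 0.20


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` is indexed by gene symbol with columns: effect_class,
    base_mean, dispersion, lfc_e2, lfc_kd, lfc_interaction,
    chromatin_state, arid1a_bound, se_mode.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["base_mean"] <= 0).any() or (t["dispersion"] <= 0).any():
            raise ValueError("base_mean and dispersion must be positive")
        coop = t["effect_class"].str.startswith("coop")
        if (np.sign(t.loc[coop, "lfc_e2"]) == np.sign(t.loc[coop, "lfc_kd"])).any():
            raise ValueError("cooperative genes must have opposite-signed E2/KD effects")
        antag = t["effect_class"].str.startswith("antag")
        if (np.sign(t.loc[antag, "lfc_e2"]) != np.sign(t.loc[antag, "lfc_kd"])).any():
            raise ValueError("antagonistic genes must have same-signed E2/KD effects")
        dep = t["effect_class"] == "dependent-induction"
        if ((t.loc[dep, "lfc_e2"] <= 0) | (t.loc[dep, "lfc_interaction"] >= 0)).any():
            raise ValueError("dependent-induction requires lfc_e2 > 0 and negative interaction")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def _allocate(n: int, fractions: dict[str, float], labels: tuple[str, ...],
              default: str, rng: np.random.Generator) -> np.ndarray:
    """Exact integer allocation of class labels, shuffled reproducibly."""
    total = sum(fractions.values())
    if total > 1 + 1e-12:
        raise ValueError(f"fractions sum to {total} > 1")
    out: list[str] = []
    for name, frac in fractions.items():
        if name not in labels:
            raise ValueError(f"unknown label {name!r}")
        out.extend([name] * int(round(frac * n)))
    if len(out) > n:
        raise ValueError("rounded fractions exceed the gene count")
    out.extend([default] * (n - len(out)))
    arr = np.array(out)
    rng.shuffle(arr)
    return arr


def generate_truth(
    n_genes: int = 2000,
    class_fractions: dict[str, float] | None = None,
    seed: int = 0,
    state_fractions: dict[str, float] | None = None,
    se_fractions: dict[str, float] | None = None,
    arid1a_fraction: float = DEFAULT_ARID1A_FRACTION,
    lfc_range: tuple[float, float] = (1.0, 2.0),
    n_chroms: int = 2,
) -> tuple[SyntheticTruth, GeneAnnotation]:
    """Plant per-gene effect classes, chromatin states and binding.

    Effect sizes default to |log2FC| in [1, 2] for cooperative/antagonistic
    classes: strong effects, detectable at n = 3 under a stringent FDR.
    Dependent-induction genes emulate abundant, strongly induced hormone
    targets: base mean log-normal(7, 0.7), induction log2FC in [2.5, 3.5]
    and an interaction of -(induction - U(0.5, 1)) so that induction
    survives knockdown but is sharply attenuated (a PGR-like ~75 percent
    reduction).
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    rng = np.random.default_rng(seed)
    class_fractions = DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions
    state_fractions = DEFAULT_STATE_FRACTIONS if state_fractions is None else state_fractions
    se_fractions = DEFAULT_SE_FRACTIONS if se_fractions is None else se_fractions

    classes = _allocate(n_genes, class_fractions, EFFECT_CLASSES, "null", rng)
    states = _allocate(n_genes, state_fractions, CHROMATIN_STATES, "neither", rng)
    se_mode = _allocate(n_genes, se_fractions, SE_MODES, "none", rng)
    bound = rng.random(n_genes) < arid1a_fraction

    base_mean = rng.lognormal(mean=5.0, sigma=1.5, size=n_genes)
    dep = classes == "dependent-induction"
    base_mean[dep] = rng.lognormal(mean=7.0, sigma=0.7, size=int(dep.sum()))
    # overdispersion inverse to abundance, clipped to [0.05, 0.4]
    dispersion = np.clip(0.05 + 3.5 / base_mean, 0.05, 0.4)

    lo, hi = lfc_range
    if not 0 < lo <= hi:
        raise ValueError("lfc_range must satisfy 0 < lo <= hi")
    mag_e2 = rng.uniform(lo, hi, n_genes)
    mag_kd = rng.uniform(lo, hi, n_genes)

    lfc_e2 = np.zeros(n_genes)
    lfc_kd = np.zeros(n_genes)
    lfc_int = np.zeros(n_genes)
    lfc_e2[classes == "coop-up"] = mag_e2[classes == "coop-up"]
    lfc_kd[classes == "coop-up"] = -mag_kd[classes == "coop-up"]
    lfc_e2[classes == "coop-down"] = -mag_e2[classes == "coop-down"]
    lfc_kd[classes == "coop-down"] = mag_kd[classes == "coop-down"]
    lfc_e2[classes == "antag-up"] = mag_e2[classes == "antag-up"]
    lfc_kd[classes == "antag-up"] = mag_kd[classes == "antag-up"]
    lfc_e2[classes == "antag-down"] = -mag_e2[classes == "antag-down"]
    lfc_kd[classes == "antag-down"] = -mag_kd[classes == "antag-down"]
    n_dep = int(dep.sum())
    induction = rng.uniform(2.5, 3.5, n_dep)
    residual = rng.uniform(0.5, 1.0, n_dep)
    lfc_e2[dep] = induction
    lfc_int[dep] = -(induction - residual)

    genes = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene")
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "effect_class": classes,
                "base_mean": base_mean,
                "dispersion": dispersion,
                "lfc_e2": lfc_e2,
                "lfc_kd": lfc_kd,
                "lfc_interaction": lfc_int,
                "chromatin_state": states,
                "arid1a_bound": bound,
                "se_mode": se_mode,
            },
            index=genes,
        )
    )

    per_chrom = int(np.ceil(n_genes / n_chroms))
    chroms = [f"chrS{i // per_chrom + 1}" for i in range(n_genes)]
    offset = (np.arange(n_genes) % per_chrom + 1) * TSS_SPACING
    jitter = rng.integers(-20_000, 20_001, n_genes)  # grid spacing keeps >=10 kb apart
    strand = rng.choice(["+", "-"], n_genes)
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"chrom": chroms, "strand": strand, "tss": offset + jitter},
            index=genes,
        )
    )
    return truth, annotation


def generate_counts(
    truth: SyntheticTruth,
    n_reps: int = 3,
    lib_sizes: np.ndarray | None = None,
    seed: int = 0,
) -> CountExperiment:
    """Draw NB counts for the 2x2 design.

    Sample j in design cell (kd, e2) has mean
    ``base_mean * lib_j * 2**(x_e2*lfc_e2 + x_kd*lfc_kd + x_e2*x_kd*lfc_int)``
    with gene-wise dispersion alpha (variance = m + alpha*m**2).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    cells = [("ctrl", "veh"), ("ctrl", "e2"), ("kd", "veh"), ("kd", "e2")]
    sample_ids, kd_col, tr_col, rep_col = [], [], [], []
    for kd, tr in cells:
        for r in range(1, n_reps + 1):
            sample_ids.append(f"{kd}_{tr}_{r}")
            kd_col.append(kd)
            tr_col.append(tr)
            rep_col.append(r)
    n_samples = len(sample_ids)
    if lib_sizes is None:
        lib_sizes = np.ones(n_samples)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (n_samples,):
        raise ValueError(f"lib_sizes must have length {n_samples}")
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")

    t = truth.table
    x_e2 = np.array([1.0 if tr == "e2" else 0.0 for tr in tr_col])
    x_kd = np.array([1.0 if kd == "kd" else 0.0 for kd in kd_col])
    log2_mu = (
        np.log2(t["base_mean"].to_numpy())[:, None]
        + np.outer(t["lfc_e2"], x_e2)
        + np.outer(t["lfc_kd"], x_kd)
        + np.outer(t["lfc_interaction"], x_e2 * x_kd)
    )
    mu = 2.0**log2_mu * lib_sizes[None, :]
    alpha = t["dispersion"].to_numpy()[:, None]

    counts = np.empty(mu.shape, dtype=np.int64)
    poisson_like = np.broadcast_to(alpha, mu.shape) < 1e-8
    # NB as gamma-Poisson: shape 1/alpha, scale alpha*mu
    shape = 1.0 / np.maximum(alpha, 1e-8)
    lam = rng.gamma(np.broadcast_to(shape, mu.shape), np.maximum(alpha, 1e-8) * mu)
    lam = np.where(poisson_like, mu, lam)
    counts[:] = rng.poisson(lam)

    design = pd.DataFrame(
        {"knockdown": kd_col, "treatment": tr_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountExperiment(pd.DataFrame(counts, index=t.index, columns=sample_ids), design)


def _se_cluster_span(tss: int, mode: str) -> tuple[int, int]:
    """Deterministic enhancer-cluster placement relative to a gene's TSS.

    inside: straddles the promoter; within50kb: nearest edge 25 kb away;
    linked: 80 kb away (outside the 50 kb halo, tied by a link table).
    Cluster footprint is 7 kb (four 1 kb peaks, 2 kb apart).
    """
    if mode == "inside":
        start = tss - 3_500
    elif mode == "within50kb":
        start = tss + 25_000
    elif mode == "linked":
        start = tss + 80_000
    else:
        raise ValueError(f"no cluster for mode {mode!r}")
    return max(0, start), max(0, start) + 7_000


def generate_peaks(
    truth: SyntheticTruth,
    annotation: GeneAnnotation,
    seed: int = 0,
    decoy_fraction: float = 0.1,
    background_fraction: float = 0.15,
) -> dict[str, list[PeakSet]]:
    """Replicated peak sets consistent with the planted truth.

    Planted promoter marks (H3K4me3/H3K27me3/ARID1A) appear as overlapping
    peaks in both replicates inside the gene's 3 kb promoter window.
    Enhancer-mode genes receive a high-signal H3K27ac+ATAC cluster placed
    per mode; a fraction of 'none' genes receive weak background clusters so
    that super-enhancer ranking has a hockey-stick body. ``decoy_fraction``
    of unmarked promoters gain a single-replicate (non-consensus) peak.
    """
    if not truth.genes.equals(annotation.genes):
        raise ValueError("truth and annotation must cover the same genes in order")
    rng = np.random.default_rng(seed)
    t = truth.table.join(annotation.table)

    out: dict[str, list[PeakSet]] = {}

    def promoter_mark(mark: str, flagged: pd.Series) -> list[PeakSet]:
        reps = []
        for rep in (1, 2):
            chroms, starts, ends, signals = [], [], [], []
            for gene, row in t[flagged].iterrows():
                jitter = int(rng.integers(-400, 401))
                half = int(rng.integers(700, 1_200))
                center = row["tss"] + jitter
                chroms.append(row["chrom"])
                starts.append(max(0, center - half))
                ends.append(center + half)
                signals.append(float(rng.uniform(5, 15)))
            # single-replicate decoys at unmarked promoters (rep 1 only)
            if rep == 1 and decoy_fraction > 0:
                unmarked = t[~flagged]
                pick = rng.random(len(unmarked)) < decoy_fraction
                for gene, row in unmarked[pick].iterrows():
                    chroms.append(row["chrom"])
                    starts.append(max(0, row["tss"] - 500))
                    ends.append(row["tss"] + 500)
                    signals.append(float(rng.uniform(1, 4)))
            reps.append(make_peakset(mark, rep, chroms, starts, ends, signals))
        return reps

    has_k4 = t["chromatin_state"].isin(["bivalent", "K4-only"])
    has_k27 = t["chromatin_state"].isin(["bivalent", "K27-only"])
    out["H3K4me3"] = promoter_mark("H3K4me3", has_k4)
    out["H3K27me3"] = promoter_mark("H3K27me3", has_k27)
    out["ARID1A"] = promoter_mark("ARID1A", t["arid1a_bound"])

    # enhancer clusters: 4 peaks of 1 kb, 2 kb apart; strong signal for SE
    # genes, weak for background clusters on a subset of 'none' genes
    none_genes = t[t["se_mode"] == "none"]
    background_pick = rng.random(len(none_genes)) < background_fraction
    bg_genes = set(none_genes.index[background_pick])

    for mark in ("H3K27ac", "ATAC"):
        reps = []
        for rep in (1, 2):
            chroms, starts, ends, signals = [], [], [], []
            for gene, row in t.iterrows():
                mode = row["se_mode"]
                if mode != "none":
                    span_start, _ = _se_cluster_span(int(row["tss"]), mode)
                    strong = True
                elif gene in bg_genes:
                    span_start = int(row["tss"]) + 100_000
                    strong = False
                else:
                    continue
                for k in range(4):
                    s = span_start + 2_000 * k + int(rng.integers(-100, 101))
                    chroms.append(row["chrom"])
                    starts.append(max(0, s))
                    ends.append(max(0, s) + 1_000)
                    signals.append(
                        float(rng.uniform(50, 100)) if strong else float(rng.uniform(1, 5))
                    )
            reps.append(make_peakset(mark, rep, chroms, starts, ends, signals))
        out[mark] = reps
    return out


def generate_links(
    truth: SyntheticTruth,
    annotation: GeneAnnotation,
    seed: int = 0,
    n_decoys: int = 50,
) -> EnhancerGeneLinks:
    """Enhancer-gene link rows mirroring the planted 'linked' clusters.

    Linked genes get a high-confidence row (score in (1.5, 10]); decoy rows
    with score <= 1 (filtered by the strict score > 1 rule) and rows pointing
    at non-enhancer loci are added as negatives.
    """
    rng = np.random.default_rng(seed)
    t = truth.table.join(annotation.table)
    rows = []
    for gene, row in t[t["se_mode"] == "linked"].iterrows():
        start, end = _se_cluster_span(int(row["tss"]), "linked")
        rows.append((row["chrom"], start, end, gene, float(rng.uniform(1.5, 10))))
        # sub-threshold duplicate: must be ignored by the score > 1 filter
        rows.append((row["chrom"], start, end, gene, float(rng.uniform(0.1, 1.0))))
    others = t[t["se_mode"] == "none"]
    pick = rng.choice(len(others), size=min(n_decoys, len(others)), replace=False)
    for i in pick:
        row = others.iloc[i]
        start = int(row["tss"]) + 150_000
        rows.append((row["chrom"], start, start + 2_000, others.index[i],
                     float(rng.uniform(1.5, 10))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "score"])
    return EnhancerGeneLinks(df.sort_values(["chrom", "start", "gene"]).reset_index(drop=True))


def planted_gene_sets(truth: SyntheticTruth, min_size: int = 10) -> GeneSetCollection:
    """Gene sets built from planted effect classes (for enrichment tests)."""
    sets = {}
    for cls in EFFECT_CLASSES:
        if cls == "null":
            continue
        members = truth.table.index[truth.table["effect_class"] == cls]
        if len(members) >= min_size:
            sets[f"PLANTED_{cls.upper().replace('-', '_')}"] = list(members)
    if not sets:
        raise ValueError("no planted class reaches min_size")
    return make_collection(sets)


def generate_crosssample_panel(
    n_samples: int = 56,
    n_marked: int = 20,
    expression_ratio: float = 0.2,
    seed: int = 0,
    target_tss: int = 500_000,
    chrom: str = "chrP",
) -> tuple[np.ndarray, list[PeakSet]]:
    """Multi-tissue panel: one expression value and one peak set per sample.

    Marked samples carry an H3K27me3 peak near ``target_tss`` and draw
    expression from the unmarked distribution scaled by ``expression_ratio``
    (RPKM-like log-normal). Unmarked samples get a distal peak only, so every
    sample has a non-empty peak set.
    """
    if not 0 < n_marked < n_samples:
        raise ValueError("need 0 < n_marked < n_samples")
    if expression_ratio <= 0:
        raise ValueError("expression_ratio must be positive")
    rng = np.random.default_rng(seed)
    marked = np.zeros(n_samples, dtype=bool)
    marked[rng.choice(n_samples, size=n_marked, replace=False)] = True

    base = rng.lognormal(mean=np.log(30.0), sigma=0.5, size=n_samples)
    expression = np.where(marked, base * expression_ratio, base)

    peaksets = []
    for i in range(n_samples):
        chroms, starts, ends = [], [], []
        if marked[i]:
            offset = int(rng.integers(-2_000, 2_001))
            chroms.append(chrom)
            starts.append(max(0, target_tss + offset - 750))
            ends.append(target_tss + offset + 750)
        # distal domain well outside any plausible promoter window
        chroms.append(chrom)
        starts.append(target_tss + 60_000)
        ends.append(target_tss + 75_000)
        peaksets.append(make_peakset("H3K27me3", i + 1, chroms, starts, ends))
    return expression, peaksets


def truth_digest(truth: SyntheticTruth) -> str:
    """Stable content hash of a truth table (provenance for run logs)."""
    h = hashlib.sha256()
    h.update(truth.table.to_csv().encode())
    return h.hexdigest()[:12]
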