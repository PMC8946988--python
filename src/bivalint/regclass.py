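"""Joint E2/knockdown regulation classes and intersection analyses.

A gene significantly regulated by both perturbations is *cooperative* when
the estrogen effect and the knockdown effect have opposite signs (normal
factor function works with estrogen: losing it flips the estrogen response)
and *antagonistic* when the two effects share a sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexpr import DEResult
from .io_formats import GeneSetCollection

JOINT_CLASSES = (
    "coop-e2up", "coop-e2down", "antag-up", "antag-down",
    "e2-only", "kd-only", "neither",
)


@dataclass(frozen=True)
class RegulatoryClassTable:
    """Per-gene joint regulation classification.

    ``table``: index gene; columns sig_e2, sig_kd (bool), dir_e2, dir_kd
    ('up'/'down'/'ns'), joint_class (one of JOINT_CLASSES).
    """

    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def _direction(de: DEResult, alpha: float) -> tuple[pd.Series, pd.Series]:
    sig = de.table["qvalue"] < alpha
    lfc = de.table["log2fc"]
    direction = pd.Series("ns", index=de.genes)
    direction[sig & (lfc > 0)] = "up"
    direction[sig & (lfc < 0)] = "down"
    # q < alpha with log2fc exactly 0 carries no direction; treated as ns
    return sig, direction


def classify_joint(
    de_e2: DEResult,
    de_kd: DEResult,
    alpha: float = 1e-4,
) -> tuple[RegulatoryClassTable, dict[str, float]]:
    """Classify every gene by its joint E2/knockdown response.

    Returns the per-gene table and summary fractions of cooperative and
    antagonistic genes among the doubly (directionally) significant ones.
    """
    if not de_e2.genes.equals(de_kd.genes):
        raise ValueError("DE results cover different gene universes")
    sig_e2, dir_e2 = _direction(de_e2, alpha)
    sig_kd, dir_kd = _direction(de_kd, alpha)

    d_e2 = dir_e2 != "ns"
    d_kd = dir_kd != "ns"
    joint = pd.Series("neither", index=de_e2.genes)
    joint[d_e2 & ~d_kd] = "e2-only"
    joint[~d_e2 & d_kd] = "kd-only"
    both = d_e2 & d_kd
    same = dir_e2 == dir_kd
    joint[both & ~same & (dir_e2 == "up")] = "coop-e2up"
    joint[both & ~same & (dir_e2 == "down")] = "coop-e2down"
    joint[both & same & (dir_e2 == "up")] = "antag-up"
    joint[both & same & (dir_e2 == "down")] = "antag-down"

    table = pd.DataFrame(
        {"sig_e2": sig_e2, "sig_kd": sig_kd, "dir_e2": dir_e2, "dir_kd": dir_kd,
         "joint_class": joint},
        index=de_e2.genes,
    )
    n_both = int(both.sum())
    n_coop = int(joint.isin(["coop-e2up", "coop-e2down"]).sum())
    n_antag = int(joint.isin(["antag-up", "antag-down"]).sum())
    summary = {
        "n_doubly_significant": n_both,
        "cooperative_fraction": n_coop / n_both if n_both else float("nan"),
        "antagonistic_fraction": n_antag / n_both if n_both else float("nan"),
    }
    return RegulatoryClassTable(table), summary


def dependent_induction_genes(
    de_e2: DEResult,
    de_delta: DEResult,
    de_interaction: DEResult,
    gene_sets: GeneSetCollection | None = None,
    set_names: list[str] | None = None,
    mode: str = "interaction",
    alpha: float = 1e-4,
    alpha_secondary: float = 0.05,
) -> list[str]:
    """Genes induced by E2 but significantly less so after knockdown.

    ``mode='interaction'``: E2 up-regulation at ``alpha`` plus a significant
    negative interaction term at ``alpha_secondary``. ``mode='delta'``:
    the within-knockdown E2 response (kd+e2 vs kd) is significant at
    ``alpha_secondary`` yet smaller than the control-background E2 response.
    Optionally restrict to the union of named gene sets (e.g. estrogen
    response pathways).
    """
    if mode not in ("interaction", "delta"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (de_e2.genes.equals(de_delta.genes) and de_e2.genes.equals(de_interaction.genes)):
        raise ValueError("DE results cover different gene universes")
    e2_up = (de_e2.table["qvalue"] < alpha) & (de_e2.table["log2fc"] > 0)
    if mode == "interaction":
        attenuated = (
            (de_interaction.table["qvalue"] < alpha_secondary)
            & (de_interaction.table["log2fc"] < 0)
        )
    else:
        attenuated = (
            (de_delta.table["qvalue"] < alpha_secondary)
            & (de_delta.table["log2fc"] < de_e2.table["log2fc"])
        )
    genes = set(de_e2.genes[e2_up & attenuated])
    if gene_sets is not None:
        names = set_names if set_names is not None else gene_sets.names()
        members: set[str] = set()
        for name in names:
            members |= gene_sets[name]
        genes &= members
    return sorted(genes)


def intersect_de_with_binding(
    de_e2: DEResult,
    de_kd: DEResult,
    bound_genes: set[str],
    alpha: float = 1e-4,
) -> tuple[dict[str, int], list[str]]:
    """Three-way overlap of E2-DE genes, knockdown-DE genes and bound genes.

    Returns all seven exclusive Euler region counts plus the central
    (triple) intersection gene list. Bound genes outside the DE universe
    are ignored.
    """
    if not de_e2.genes.equals(de_kd.genes):
        raise ValueError("DE results cover different gene universes")
    universe = set(de_e2.genes)
    A = set(de_e2.significant(alpha))
    B = set(de_kd.significant(alpha))
    C = {g.upper() for g in bound_genes} & universe
    regions = {
        "e2_only": len(A - B - C),
        "kd_only": len(B - A - C),
        "bound_only": len(C - A - B),
        "e2_kd": len((A & B) - C),
        "e2_bound": len((A & C) - B),
        "kd_bound": len((B & C) - A),
        "e2_kd_bound": len(A & B & C),
    }
    return regions, sorted(A & B & C)


def four_group_segregation(table: RegulatoryClassTable) -> dict[str, list[str]]:
    """Partition doubly-significant genes by (E2 direction, KD direction)."""
    t = table.table
    both = t["joint_class"].isin(["coop-e2up", "coop-e2down", "antag-up", "antag-down"])
    groups = {}
    for e2_dir in ("up", "down"):
        for kd_dir in ("up", "down"):
            sel = both & (t["dir_e2"] == e2_dir) & (t["dir_kd"] == kd_dir)
            groups[f"e2{e2_dir}_kd{kd_dir}"] = sorted(t.index[sel])
    return groups
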