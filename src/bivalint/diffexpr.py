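"""Negative-binomial differential expression for the 2x2 factorial design.

The model is a saturated NB log-linear model on median-of-ratios-normalized
counts: with one parameter per design cell, the maximum-likelihood fitted
cell mean (for fixed dispersion) is the sample mean of the normalized counts
in that cell, so no iterative fit is needed. Contrasts are differences of
log2 cell means; Wald standard errors come from the NB Fisher information
with a gene-wise dispersion estimated by method of moments and shrunk
halfway toward a fitted mean-dispersion trend.

Multiple testing uses a covariate-weighted Benjamini-Hochberg procedure
(quantile bins on the mean-expression covariate, data-driven per-bin
weights with mean one), an approximation to independent hypothesis
weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountExperiment

LN2 = np.log(2.0)

CONTRASTS = ("e2_vs_ctrl", "kd_vs_ctrl", "kd+e2_vs_kd", "kd+e2_vs_e2", "interaction")

# design cells keyed as (knockdown, treatment)
_CELLS = (("ctrl", "veh"), ("ctrl", "e2"), ("kd", "veh"), ("kd", "e2"))

# contrast -> coefficients on the four log cell means, cell order as _CELLS
_CONTRAST_COEF = {
    "e2_vs_ctrl": np.array([-1.0, 1.0, 0.0, 0.0]),
    "kd_vs_ctrl": np.array([-1.0, 0.0, 1.0, 0.0]),
    "kd+e2_vs_kd": np.array([0.0, 0.0, -1.0, 1.0]),
    "kd+e2_vs_e2": np.array([0.0, -1.0, 0.0, 1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}

# floor on a fitted cell mean: keeps log fold changes finite for all-zero
# cells while inflating their variance so such genes never reach significance
_MEAN_FLOOR = 0.125


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential expression statistics for one contrast.

    ``table``: index gene; columns base_mean, log2fc, se, wald_stat,
    pvalue, qvalue.
    """

    table: pd.DataFrame
    contrast: str

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha: float) -> pd.Index:
        return self.table.index[self.table["qvalue"] < alpha]


def filter_low_counts(expt: CountExperiment, min_mean: float = 1.0) -> CountExperiment:
    """Drop genes with mean raw count below ``min_mean`` (inclusive boundary:
    a gene averaging exactly ``min_mean`` is retained)."""
    totals = expt.counts.sum(axis=1)
    keep = totals >= min_mean * expt.counts.shape[1]
    return CountExperiment(expt.counts.loc[keep], expt.design)


def size_factors(expt: CountExperiment) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    Only genes with nonzero counts in every sample enter the reference.
    """
    counts = expt.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; size factors need a "
            "pseudo-reference (filter or pool samples first)"
        )
    ref = counts[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=expt.samples, name="size_factor")


def _cell_indices(expt: CountExperiment) -> list[np.ndarray]:
    design = expt.design
    idx = []
    for kd, tr in _CELLS:
        sel = np.flatnonzero((design["knockdown"] == kd).values & (design["treatment"] == tr).values)
        idx.append(sel)
    return idx


def _trend_dispersion(alpha_raw: np.ndarray, mu: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Fit the mean-dispersion trend alpha(mu) = a0 + a1/mu.

    Genes are grouped into quantile bins of mu and the bin-wise mean of the
    raw dispersion is regressed on 1/mu (count-weighted); binning keeps the
    extreme low-count moment estimates from dominating the fit. Falls back
    to the overall median when too few genes.
    """
    ok = np.isfinite(alpha_raw) & (mu > 0)
    if ok.sum() < 10 * 2:
        return np.full_like(mu, max(float(np.nanmedian(alpha_raw)), 1e-8))
    a, m = alpha_raw[ok], mu[ok]
    order = np.argsort(m, kind="mergesort")
    edges = np.linspace(0, len(order), min(n_bins, max(2, len(order) // 25)) + 1).astype(int)
    bin_mu, bin_alpha, bin_n = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        if len(idx) == 0:
            continue
        bin_mu.append(float(np.mean(m[idx])))
        bin_alpha.append(float(np.mean(a[idx])))
        bin_n.append(len(idx))
    X = np.column_stack([np.ones(len(bin_mu)), 1.0 / np.asarray(bin_mu)])
    w = np.sqrt(np.asarray(bin_n, dtype=float))
    coef, *_ = np.linalg.lstsq(X * w[:, None], np.asarray(bin_alpha) * w, rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = max(float(np.median(a)), 1e-8)
    return a0 + a1 / np.maximum(mu, 1e-8)


class FactorialFit:
    """One NB fit of the full 2x2 design; contrasts are read off it.

    Fitting once and extracting several contrasts keeps the dispersion and
    the normalization shared across all reported comparisons.
    """

    def __init__(self, expt: CountExperiment, sf: pd.Series | None = None):
        for idx in _cell_indices(expt):
            if len(idx) < 2:
                raise ValueError("every design cell needs >= 2 replicates")
        self.expt = expt
        self.sf = size_factors(expt) if sf is None else sf
        counts = expt.counts.to_numpy(dtype=float)
        norm = counts / self.sf.to_numpy()[None, :]
        self.norm = norm
        self.base_mean = norm.mean(axis=1)

        cells = _cell_indices(expt)
        self.n_cells = np.array([len(c) for c in cells])
        self.cell_means = np.column_stack([norm[:, c].mean(axis=1) for c in cells])

        # cell-wise method of moments on normalized counts: within each design
        # cell E[s2_c] = mu_c + alpha*mu_c^2, so alpha is estimated from the
        # df-weighted excess variance over all cells (for a gene with equal
        # cell means this reduces to (s2 - mu)/mu^2 on the pooled values)
        num = np.zeros(norm.shape[0])
        den = np.zeros(norm.shape[0])
        for j, c in enumerate(cells):
            m_c = self.cell_means[:, j]
            s2_c = norm[:, c].var(axis=1, ddof=1)
            df = len(c) - 1
            num += df * (s2_c - m_c)
            # E[m_c^2] = mu_c^2 + sigma_c^2/n_c; subtract the bias so alpha
            # is not systematically underestimated at small n
            den += df * np.maximum(m_c**2 - s2_c / len(c), 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_raw = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        alpha_raw = np.clip(alpha_raw, 0.0, 10.0)
        mu = self.base_mean
        trend = np.clip(_trend_dispersion(alpha_raw, mu), 0.0, 10.0)
        self.dispersion = np.clip(0.5 * alpha_raw + 0.5 * trend, 1e-8, 10.0)

    def contrast(
        self,
        name: str,
        alpha: float = 1e-4,
        n_bins: int = 5,
    ) -> DEResult:
        """Wald test of a named linear contrast of log2 cell means."""
        if name not in _CONTRAST_COEF:
            raise ValueError(f"unknown contrast {name!r}; one of {CONTRASTS}")
        coef = _CONTRAST_COEF[name]
        m = np.maximum(self.cell_means, _MEAN_FLOOR)
        log2m = np.log2(m)
        lfc = log2m @ coef
        # Fisher information of a log cell mean: n*m/(1+alpha*m)
        var_ln = (1.0 + self.dispersion[:, None] * m) / (self.n_cells[None, :] * m)
        var = (var_ln * coef[None, :] ** 2).sum(axis=1)
        se = np.sqrt(var) / LN2
        with np.errstate(invalid="ignore"):
            z = np.where(se > 0, lfc / se, 0.0)
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
        qvalue = weighted_fdr(pvalue, self.base_mean, n_bins=n_bins, alpha=alpha)
        table = pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "log2fc": lfc,
                "se": se,
                "wald_stat": z,
                "pvalue": pvalue,
                "qvalue": qvalue,
            },
            index=self.expt.genes,
        )
        return DEResult(table, name)


def fit_contrast(
    expt: CountExperiment,
    contrast: str,
    alpha: float = 1e-4,
    n_bins: int = 5,
) -> DEResult:
    """Fit the factorial NB model and return one contrast's statistics."""
    return FactorialFit(expt).contrast(contrast, alpha=alpha, n_bins=n_bins)


# ---------------------------------------------------------------------------
# Covariate-weighted FDR
# ---------------------------------------------------------------------------

def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out

_WEIGHT_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def weighted_fdr(
    pvalues: np.ndarray,
    covariate: np.ndarray,
    n_bins: int = 5,
    alpha: float = 0.05,
) -> np.ndarray:
    """Covariate-weighted BH q-values (an IHW-style approximation).

    Hypotheses are binned by covariate quantiles; a grid search over
    per-bin weights (mean one across hypotheses) picks the weighting that
    maximizes rejections at ``alpha``; q-values are global BH on p/w.
    With ``n_bins=1`` this is exactly plain BH.
    """
    p = np.asarray(pvalues, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if p.ndim != 1 or cov.shape != p.shape:
        raise ValueError("pvalues and covariate must be 1-D and equal length")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be finite")
    n = len(p)
    if n == 0:
        return p.copy()
    if n_bins <= 1:
        return _bh(p)

    # quantile bins on the covariate (ranked to break ties deterministically)
    ranks = stats.rankdata(cov, method="ordinal")
    bins = np.minimum(((ranks - 1) * n_bins) // n, n_bins - 1).astype(int)
    n_per_bin = np.bincount(bins, minlength=n_bins)

    best_q = _bh(p)
    best_rej = int((best_q < alpha).sum())
    best_key = (0.0,)  # uniform weights preferred on ties
    from itertools import product

    seen: set[tuple[float, ...]] = set()
    for combo in product(_WEIGHT_GRID, repeat=n_bins):
        w = np.asarray(combo, dtype=float)
        w = w / (np.dot(n_per_bin, w) / n)  # mean weight over hypotheses = 1
        key = tuple(np.round(w, 12))
        if key in seen:
            continue
        seen.add(key)
        wp = np.minimum(p / w[bins], 1.0)
        q = _bh(wp)
        rej = int((q < alpha).sum())
        spread = float(np.abs(np.log(w)).sum())
        if rej > best_rej or (rej == best_rej and spread < best_key[0]):
            best_rej, best_q, best_key = rej, q, (spread,)
    return best_q


# ---------------------------------------------------------------------------
# Variance-stabilized transform, variable genes, PCA
# ---------------------------------------------------------------------------

def rlog_like(expt: CountExperiment, sf: pd.Series, pseudocount: float = 4.0) -> pd.DataFrame:
    """Fixed-pseudocount log2 of normalized counts: log2(count/sf + c), c=4.

    An approximation to a regularized-log transform, adequate for variance
    ranking and clustering; it is not a shrinkage estimator.
    """
    norm = expt.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + pseudocount), index=expt.genes, columns=expt.samples)


def select_variable_genes(
    mat: pd.DataFrame,
    min_variance: float | None = 0.05,
    top_n: int | None = None,
) -> list[str]:
    """Variable-gene selection: threshold mode (row variance strictly above
    ``min_variance``) or top-N mode; exactly one must be chosen."""
    if (min_variance is None) == (top_n is None):
        raise ValueError("set exactly one of min_variance or top_n")
    vals = mat.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("matrix must be finite")
    var = vals.var(axis=1, ddof=1)
    if top_n is not None:
        order = sorted(zip(-var, mat.index), key=lambda t: (t[0], t[1]))
        return [g for _, g in order[:top_n]]
    return [g for g, v in zip(mat.index, var) if v > min_variance]


def pca(mat: pd.DataFrame, top_n: int | None = 500) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the top-N variable genes (gene-centered).

    Returns sample coordinates (samples x components) and the explained
    variance fractions.
    """
    from sklearn.decomposition import PCA

    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if top_n is not None and top_n < mat.shape[0]:
        genes = select_variable_genes(mat, min_variance=None, top_n=top_n)
        mat = mat.loc[genes]
    X = mat.to_numpy(dtype=float).T  # samples x genes
    n_comp = min(X.shape[0], X.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    coords = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=mat.columns, columns=cols),
        model.explained_variance_ratio_,
    )
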