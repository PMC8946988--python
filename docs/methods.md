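# Methods

## Scientific setting

Endometrial epithelial cells respond to estrogen (E2) through ESR1; induction
of the progesterone receptor gene (*PGR*) is the critical negative-feedback
readout. The SWI/SNF chromatin-remodeling subunit ARID1A is required for the
induction of a subset of estrogen targets: its loss leaves PRC2-deposited
H3K27me3 unopposed at promoters that carry both the repressive H3K27me3 and
the activating H3K4me3 mark ("bivalent" promoters, poised between silencing
and activation). The package implements the quantitative chain of such a
study — factorial differential expression, co-regulation classification,
promoter-state calling, enrichment statistics, super-enhancer association,
gene-set enrichment, and a cross-tissue promoter-mark comparison — with a
synthetic-data module that plants known effects so every stage's recovery is
testable without external downloads.

## Count model and differential expression

Counts are modeled as negative binomial, `Var = μ + αμ²`. Normalization is
median-of-ratios: per-sample factors are medians of count-to-geometric-mean
ratios over genes with nonzero counts in every sample, rescaled to geometric
mean 1. Genes averaging fewer than 1 raw count per sample are removed first
(boundary inclusive: a gene averaging exactly 1 is kept).

The 2×2 design (knockdown ∈ {ctrl, kd} × treatment ∈ {veh, e2}) is fitted
saturated, one parameter per design cell. For fixed dispersion, the NB score
equation makes the MLE of a cell mean the sample mean of the normalized
counts in that cell, so no iterative fit is required. A contrast is a linear
combination of log2 cell means; its variance comes from the NB Fisher
information, `Var(log m̂_c) = (1 + α m_c) / (n_c m_c)`, summed over the
involved cells with squared contrast coefficients. The Wald statistic is
`log2FC / SE` with a two-sided normal p-value. Cell means below 0.125
(normalized counts) are floored there for the point estimate, which keeps
log fold changes finite for empty cells while their variance keeps such
genes far from significance.

**Dispersion.** Per gene, the cell-wise method of moments: within each cell
`E[s²_c] = m_c + α m_c²`, so α̂ is the df-weighted sum of excess variances
`Σ df_c (s²_c − m_c)` over `Σ df_c (m_c² − s²_c/n_c)`; the denominator
subtracts the `E[m̂²] = μ² + σ²/n` bias, which matters at n = 3. For a gene
with equal cell means this reduces to the pooled `(s² − μ)/μ²` form. Raw
estimates are clipped to [0, 10] and shrunk 50/50 toward a trend
`α(μ) = a₀ + a₁/μ` fitted by count-weighted least squares on quantile-bin
means of the raw estimates (binning keeps the noisy low-count estimates from
dominating). Full empirical-Bayes machinery (per-gene posteriors, outlier
handling, shrunken fold changes) is deliberately out of scope.

At the default simulation scale (2,000 genes, n = 3 per cell) the Wald test's
empirical type-I error at nominal 0.05 sits near 0.055 — the small residual
anti-conservatism of plugging an estimated dispersion into a normal reference
at 8 residual degrees of freedom.

**Weighted FDR.** An approximation to independent hypothesis weighting:
hypotheses are binned into 5 quantile bins of mean expression; per-bin
weights from the grid {¼, ½, 1, 2, 4}, normalized to mean 1 over hypotheses,
are searched for the combination maximizing rejections at the target level;
q-values are a single global BH step-up on p/w (capped at 1). Ties prefer
the most uniform weighting, and `n_bins=1` is exactly BH. The exact IHW
convex program is not reproduced.

**rlog-like transform.** `log2(count/sf + 4)` — a fixed-pseudocount
approximation used only for variance ranking, clustering and PCA, not a
shrinkage estimator. Variable genes are selected either by a strict variance
threshold (> 0.05 by default, matching the transform's scale) or as the top
N by variance (N = 500 for PCA). PCA centers genes and projects samples
(scikit-learn, full SVD).

## Co-regulation classes

Direction is the sign of log2FC among genes with q < α (default α = 10⁻⁴); a
significant gene with log2FC exactly 0 carries no direction and is treated
as non-significant for classification. Genes directionally significant in
both contrasts are *cooperative* when E2 and knockdown effects disagree in
sign and *antagonistic* when they agree; singles are e2-only/kd-only; the
seven classes partition the universe. "Dependent induction" (E2-induced,
attenuated by knockdown) defaults to the interaction criterion: E2
up-regulation at α plus a negative interaction term significant at a
secondary 0.05 level — the interaction term is one contrast tested once, so
the stringent genome-wide threshold of the primary DE screen is not re-imposed
on it. The Δ-contrast variant (`kd+e2_vs_kd` significant and smaller than the
E2 response) is exposed as `mode="delta"`.

## Promoters, consensus peaks, chromatin states

All coordinates are 0-based half-open (BED convention). Promoters are
symmetric windows on the primary TSS (3 kb total by default), strand-invariant,
clipped at position 0; the annotation supplies one primary TSS per gene and
the choice of that TSS is deferred to annotation preparation. Replicate
consensus: each replicate-1 peak overlapping (≥ 1 bp) any replicate-2 peak
contributes the union span over itself and its partners; spans are merged and
the merged region's signal is the sum of all member peaks' signals (each
counted once). Anchoring on replicate 1 is symmetric in effect after merging.
A promoter "has" a mark iff ≥ 1 bp of a consensus peak intersects its window.
States partition genes: bivalent = H3K4me3 ∧ H3K27me3.

Association statistics are the field's standard tests via scipy:
hypergeometric upper tail `P(X ≥ overlap)` for set overlaps, two-sided Fisher
exact (probability-mass summation convention) for flag pairs with a Haldane
0.5 correction applied to the odds ratio only when a table cell is zero
(flagged `degenerate`), and two-sided Wilcoxon rank-sum for expression-by-
state comparisons (groups under 3 genes warn and return NaN).

**Cross-sample comparison.** Each panel sample is binarized by presence of
any repressive-mark peak within the target window; the `window` parameter is
the total width and defaults to 6,000 (= "within 3 kb of the TSS"), wider
than the 3 kb promoter window used for state calling — both are exposed.
Group means are reported with t-based 95% CIs alongside the Wilcoxon p.

## Super-enhancers

Input is the coordinate intersection of H3K27ac and ATAC consensus peaks
(signal from H3K27ac). Peaks with gaps ≤ 12.5 kb are stitched (community
default; configurable), optionally after removing peaks fully inside TSS
windows; a stitched region's signal is the sum of member peak signals. For
the super call, regions are sorted ascending by signal, ranks and signals
scaled to [0, 1], and the cutoff placed at the first point where the discrete
slope exceeds 1 (tolerance 10⁻⁹): regions strictly above that signal level
are super-enhancers. An exact linear ramp has no crossing and yields none;
equal-signal inputs warn and yield none. Gene association: `inside`
(promoter ∩ region ≥ 1 bp), `within50kb` (edge-to-edge gap ≤ 50,000 bp,
overlap counting as 0), `linked` (link rows with score strictly > 1 whose
enhancer interval overlaps a super-enhancer). DE-gene enrichment among
associated genes is the hypergeometric test against the active-gene universe.

## Gene-set enrichment

Genes are ranked descending by the Wald statistic (or log2FC), ties broken
alphabetically. The enrichment score is the signed maximum deviation of a
running sum that rises by `|stat|^p` (p = 1, normalized over set members) at
hits and falls by `1/(N − n)` at misses; a set spanning the whole universe
scores 1 by convention, and all-zero statistics fall back to unweighted
increments. The null distribution is gene-set permutation — random same-size
sets, the appropriate scheme when n = 3 per group admits only 20 distinct
phenotype permutations — with the null shared between sets of equal size.
NES divides ES by the mean magnitude of same-signed null scores; the
empirical p counts same-signed null scores at least as extreme, with the
observed score included once; q is BH across sets. Permutation walks are
evaluated at hit positions only (the walk's extrema occur immediately before
or after hits), which makes 1,000 permutations on a 2,000-gene universe take
well under a second.

## Synthetic data: what it emulates, and what it does not

`generate_truth` plants, per gene: an effect class (cooperative up/down,
antagonistic up/down, dependent-induction, or null), a base mean
(log-normal(5, 1.5)), a dispersion inverse to abundance
(`clip(0.05 + 3.5/μ, 0.05, 0.4)`), a promoter chromatin state (defaults 5%
bivalent, 60% K4-only, 7% K27-only — chosen so ~7–8% of active promoters are
bivalent, the genome-typical minority), ARID1A promoter binding (20%), and a
super-enhancer mode (2% inside / 3% within 50 kb / 4% linked). Cooperative
and antagonistic effects draw |log2FC| from [1, 2]: strong effects, the kind
that survive an FDR < 10⁻⁴ screen at n = 3. Dependent-induction genes emulate
abundant, strongly induced hormone targets (base mean log-normal(7, 0.7),
induction log2FC in [2.5, 3.5], interaction −(induction − U(0.5, 1)) so
induction survives knockdown but is cut sharply — a PGR-like ~75% reduction);
a power analysis at n = 3 puts the sensitivity of the interaction criterion
for these settings near 0.95. Genes sit on a 200 kb TSS grid (±20 kb jitter)
across two synthetic chromosomes so that enhancer clusters placed relative to
one gene can never stray into a neighbour's 50 kb halo.

`generate_counts` draws gamma-Poisson (NB) counts with per-sample library
factors; `generate_peaks` places replicate-overlapping promoter peaks for
planted marks, decoy single-replicate peaks (removed by consensus) at a
configurable fraction of unmarked promoters, high-signal 4-peak enhancer
clusters for SE-mode genes and weak background clusters on 15% of the
remaining genes (giving the rank–signal curve its hockey-stick body);
`generate_links` writes high-confidence rows for linked genes plus
sub-threshold (score ≤ 1) and decoy rows. `generate_crosssample_panel` draws
RPKM-like log-normal expression, scaling marked samples by the expression
ratio (0.2 by default; ratio 1 plants no difference).

What passing tests on these fixtures show: the estimators and set operations
recover planted structure at realistic overdispersion and replication, with
calibrated error rates. What they do not show: robustness to features the
generator omits — outlier replicates, batch effects, GC/length biases,
correlated genes, ragged peak shapes, mappability artifacts, or annotation
ambiguity in the choice of primary TSS. Conclusions about real data still
require the usual upstream QC.

## Numerical and design choices

- Single convention everywhere: 0-based half-open intervals; gene identity is
  the uppercased symbol; no ID mapping.
- Deterministic tie-breaks: variance ranking and GSEA break ties by gene
  symbol; stitched-region ranks break ties by coordinates; every generator
  and permutation takes an explicit seed, and `run_all` derives all stage
  seeds from the config seed, making output tables byte-identical across
  reruns.
- Degenerate inputs: empty design cells are rejected; all-zero samples make
  size factors undefined (error advising a pseudo-reference); empty groups in
  the cross-sample comparison raise with the group named; equal-signal region
  lists warn and call no super-enhancers.
- The pipeline's "expressed universe" for chromatin-state analyses is the set
  of genes surviving the low-count filter.
- Default analysis scale (2,000 genes, 3 replicates, 1,000 permutations,
  100-seed power loops) keeps a full `run_all` around 3 s and the whole test
  suite under a minute, while leaving every statistical property measurable
  with useful precision.

## Known limitations

- The DE engine is a transparent re-implementation, not a DESeq2 clone: no
  empirical-Bayes dispersion posteriors, no LFC shrinkage, no outlier
  replacement; its Wald test runs ~0.5–1 point anti-conservative at n = 3.
- The weighted-FDR grid search is a coarse stand-in for IHW's convex
  optimization and can choose weights that overfit mildly at very small gene
  counts.
- The rlog-like transform is a fixed-pseudocount log, adequate for ranking
  but not for count-level inference.
- Published catalog numbers from the original cell-line datasets (absolute DE
  counts, the 12Z super-enhancer catalog, pathway NES tables) require the
  deposited sequencing data and are out of reach of the synthetic fixtures by
  design; the package's claims are calibration and recovery properties.
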