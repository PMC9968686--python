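# Methods

This note documents the models, defaults and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real data.

## Normalization

Bulk UMI counts are normalized with median-of-ratios size factors
followed by a shifted log: value = log2(count/factor + 1), tagged
`mor-log2` in outputs. The reference for the ratio is the per-gene
geometric mean over samples, restricted to genes positive in every
sample; factors are rescaled to geometric mean 1. When no gene is
positive everywhere (pathological for real bulk data, possible in tiny
simulations) the estimator falls back to library-size factors with a
logged warning. This transform is deliberately simpler than shrinkage-
based regularized-log transforms: it is monotone per sample and
variance-stabilizing enough that the cascade's detectability and
fold-change filters keep their intended semantics, which is what the
downstream analysis needs. A consequence is that the detectability
cutoff (the median of the normalized comparison submatrix) is a
quantity on *this* scale; numeric cutoff values are not portable across
normalizations and are therefore recomputed per comparison rather than
fixed.

## Single-cell QC

A cell is removed iff total UMI < 1000 OR detected genes < 500 OR
mitochondrial percentage > 15 — strict inequalities, so a cell exactly
at every threshold is retained. Metrics are recomputed from the count
matrix; mitochondrial genes are recognized by an identifier prefix
(default `mt-`, configurable). QC is idempotent. Benchmark atlases with
fewer genes than the detected-gene threshold scale that threshold to
n_genes/3, since no cell can detect 500 of 375 genes.

## Differential-expression cascade

Statistics are computed only on genes passing the detectability filter,
so the BH universe is the detectable set — the multiplicity correction
matches the set of genes actually tested. The fold-change filter is
|log2FC| ≥ log2 1.5 (difference of group means on the log2 scale);
the 3-group development contrast uses the maximum pairwise difference
among stage means. The empirical-Bayes prior (d₀, s₀²) is fitted by
the classic moment estimator on z = log s²: with
e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of Var[e] over the mean
of ψ′(d_g/2) determines d₀ by trigamma inversion (Newton iteration,
50-step cap, relative tolerance 1e-12) and s₀² follows in closed form.
No excess dispersion yields d₀ = +∞ with s₀² = mean(s²) (point-mass
prior, plain moment estimate); at d₀ = 0 the moderated t reduces
exactly to the ordinary pooled t (verified to 1e-12), and d₀ = +∞
replaces every gene's variance with s₀² (t df becomes normal, F·(k−1)
becomes χ²). Genes with zero moderated variance receive p = 0 by the
infinite-statistic convention, with a warning. Contrasts whose samples
span sequencing plates are refused (error code `E_PLATE`): plate is a
batch and the design handles it by restricting contrasts within plate,
not by regression.

## Deconvolution

The reference is built per subject and cluster: θˢ_gk is the pooled
relative expression of cluster k's cells within subject s; Θ is the
across-subject mean (columns renormalized to sum 1), T² the
across-subject variance (ddof 1; zero with a warning for single-subject
clusters), and S_k the mean total UMI per cell. Taking S from the
reference atlas is an assumption when reference and bulk species
differ; `use_cell_size=False` gives pure relative-abundance mode
(S ≡ 1).

Gene restriction keeps one-to-one orthologs present in both matrices
and in the variable-gene list (union of per-cluster marker sets, capped
at 3000, or all shared genes). Renormalizing the restricted Θ columns
rescales the regression coefficients by each cluster's captured
expression mass c_k (the pre-renormalization column sum); cell sizes
are therefore multiplied by c_k at alignment, which is what makes the
noiseless limit exact (measured max error ~3e-16 against 1e-6
tolerance). Fewer than 2·n_clusters surviving genes aborts with
`E_UNDERDETERMINED`.

Per sample, the solver iterates: weighted NNLS (Lawson–Hanson on
√w-scaled design) then weight update w_g = 1/(ν + Σ_k β_k² τ²_gk),
until max|Δβ| < 1e-6 or 1000 iterations. Defaults: ν = 1e-8·mean(x²)
(pure numerical floor), tol 1e-6. The weight update uses the mean of
the last two β iterates: the undamped fixed-point map can settle into a
two-point limit cycle (observed amplitude ~0.014 on ~1% of simulated
samples); damping preserves fixed points and removes the cycles (median
17 iterations to convergence on the demonstration cohort).
Non-convergence is reported in the result, not fatal. Estimation is per
sample — no information is pooled across samples.

Group comparisons of broad-type proportions use the two-sided Wilcoxon
rank-sum test: exact by enumeration of all C(n1+n2, n1) mid-rank
assignments when n1 + n2 ≤ 12 (the exact null is conditional on the
observed tie pattern), otherwise the normal approximation with tie
correction and a 0.5 continuity correction. Percent change is computed
on group means (undefined, reported as NaN, when the reference mean is
zero).

## Markers

One-vs-rest per cluster on library-size log-normalized per-cell
expression: Wilcoxon rank-sum (normal approximation with tie and
continuity corrections — cluster sizes are large), AUC = U/(n1·n2),
log2FC as the difference of group means on the log scale, BH within
cluster. The marker set takes adjusted p ≤ 0.05 and log2FC > 0, top 200
by AUC (all three thresholds configurable). Clusters with fewer than 3
cells are excluded with a warning.

## Patterns, enrichment, biomarkers

Profiles are z-scored per gene (constant rows become zero vectors)
before K-means (k-means++ with 10 restarts, best inertia kept; empty
clusters are relocated by the underlying implementation). Cluster
labels are deterministic given the seed: clusters are ordered by the
column index of their centroid's peak, tie-broken by descending
centroid mean, and numbered with the analysis prefix (O for
development, D for DES, K for KTZ, P for shared). The k defaults
(3/6/8/4) are fixed conventions of the analysis, not data-derived.

Enrichment uses the one-sided hypergeometric upper tail per (pattern,
term) pair, BH-adjusted jointly across all pairs of an analysis; the
enrichment call requires adjusted p ≤ 0.05 AND overlap ≥ 2. The
universe is the union of detectable genes over the analysis's
contrasts — the set of genes that could have been called. Terms
disjoint from the universe are skipped with a warning.

Signature intersection takes the union of each compound's calls over
all conditions; a shared gene's direction class per compound is "over"
if every significant call is up, "under" if every call is down, else
"mixed". The biomarker rule is evaluated per (gene, compound, stage):
same-direction calls at ≥ 2 of 3 doses nominate the gene, direction
conflicts disqualify it, and support at every dose sets the all-dose
flag.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design's structure: 3 stages ×
(control + 3 doses) × 2 compounds with 6 replicates (the real design
used 5–8) and one plate per compound carrying its own controls; an
atlas of 8 clusters covering 8 of the 10 broad ovarian cell types
(erythrocytes and perivascular cells, rare in tissue, are omitted from
the default spec, which is itself configurable); germ-cell proportions
falling ~80% from PND6 to PND22 with granulosa, steroidogenic granulosa
and theca rising. Bulk expectations are exact cell-size-weighted
mixtures of cluster profiles; planted effects multiply the affected
gene's expectation by 2^log2FC without renormalization, so the
planted ratio is realized exactly in expectation. Noise is negative
binomial with a single cohort-level size parameter (default 10, the
standard UMI model); subject variability is a per-gene log-normal
factor of scale 0.3; markers are elevated 8-fold over the gene's
maximum across clusters. Default planted |log2FC| values lie in
0.8–2 — a simulation choice, as real effect sizes for these exposures
are not established. Exposure effects are planted on genes expressed
above the mixture median: an effect on a gene below the detection
background is invisible to any pipeline by construction, and the
power benchmark measures the statistics, not the detectability screen.

Not emulated: read-level artifacts, doublet expression profiles,
batch chemistry beyond plate structure, dropout beyond what the NB
produces, ambient RNA, and cross-species divergence of ortholog
expression (the ortholog map renames genes; it does not distort their
profiles). Passing tests therefore establish correctness of the
machinery and calibration under the stated noise model, not performance
on any particular real dataset.

## Benchmark problem sizes

Chosen so the full battery (tests plus acceptance script) completes in
about a minute on one CPU: deconvolution recovery over 20 seeds with
375-gene atlases, an 80% one-to-one ortholog map (~300 usable genes)
and 12-sample NB cohorts; false-discovery control over 100 null
replicates of 2000 genes at n = 6/group; power over 10 seeds with 50
planted |log2FC| = 1.5 effects at n = 8/group; empirical-Bayes recovery
on 5000 prior-simulated variances; pattern recovery over 20 seeds of 90
genes. Measured values at seed 1: broad-type MAE 0.040 (tolerance
0.05), noiseless error 3e-16 (1e-6), mean FDP 0.05 (0.07), power 0.98
(0.80), prior-parameter errors 2.3%/1.8% (15%), minimum ARI 1.0 (0.9).

## Known limitations

- The moderated F for the development contrast assumes a common
  within-group variance across stages; strong heteroscedasticity
  across stages is not modeled.
- The deconvolution weights use a first-order propagation of reference
  variance (τ² enters through the current β); no uncertainty is
  attached to the estimated proportions.
- The enrichment model treats gene sets as flat (no ontology-graph
  propagation), and the universe choice (detectable genes) matters:
  a whole-genome universe would inflate significance.
- Percent changes in proportion comparisons are mean-based and
  sensitive to outliers at small n; the test itself is rank-based.
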