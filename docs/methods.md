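# Methods

This note documents the models and procedures spotflow implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Data model and geometry

A `SpotDataset` holds one tissue section: a gene × spot integer count matrix
(sparse), per-spot Visium array coordinates, optional pathologist
annotations from a controlled vocabulary, and, for synthetic data, the
attached ground truth. All matrices are keyed by spot barcode, never by
positional index, so QC subsetting cannot silently misalign layers.

Array coordinates `(row, col)` (constant row+col parity) map to canonical
coordinates `x = col/2`, `y = row·√3/2`. This is the one convention under
which the three distance thresholds used throughout (≤ 2 for surrounding
spots; < 2 and ≥ 2.5 for zoning) partition the hexagonal rings
non-degenerately: ring distances are 1, √3, 2, √7 ≈ 2.646, … so the
boundary value 2.5 never occurs on the lattice, and the half-open
assignment (intermediary = [2, 2.5)) is exhaustive. Because exact lattice
distances acquire ~1e-15 floating error, every threshold comparison carries
a 1e-9 tolerance.

## QC and normalization

Spots are removed when their UMI total is strictly below 500 or strictly
above 45,000, or when the mitochondrial **count** fraction (genes with the
`MT-` prefix) is strictly greater than 0.5 — a fraction of exactly 0.5 is
retained. The mitochondrial rule is read as a count fraction because a
per-spot "fraction of genes" is not well defined. QC is idempotent and
report-based (every removed spot is listed with its reasons).

Normalization is `log1p(count · m / spot_total)` with `m` the median spot
total ("log-CPM-median"). This is a deliberate, documented stand-in for
variance-stabilizing transforms: every downstream statistic here is either
rank-based (Wilcoxon, TF activity, AUC) or z-scored per gene (pathway
activity, importance model), so the flavor of variance stabilization does
not change results qualitatively. The method name is recorded in output
metadata.

Pseudo-bulk sums raw counts over spot groups, computes counts-per-million
per group, and keeps a gene only when its raw sum is ≥ 50 in **every**
group (the filter is monotone: adding counts never removes a kept gene).

## Deconvolution stand-in

Per spot, CPM-scaled expression is regressed on the cell-type signature
matrix by non-negative least squares; proportions are `β/Σβ`. This is an
intentionally simple, solver-exact replacement for hierarchical Bayesian
deconvolution: on noiseless mixtures it recovers proportions to machine
precision, and under the package's default negative-binomial simulation
(5 cell types, 2,000 genes, library 5,000, dispersion 10, 500 spots) the
mean per-spot L1 error is ≈ 0.09. Spots with no non-negative support are
flagged `unresolved` and assigned uniform proportions rather than NaN so
that permutation statistics stay well defined; flagged spots are excluded
from enrichment by default.

## Region enrichment

For each of `n_perm` permutations (default 10,000), whole proportion rows
are shuffled across spot positions — preserving each spot's composition —
and the difference `d_p = observed − permuted` mean proportion per
(cell type, category) is recorded. The score is `mean(d_p)/sd(d_p)` with
the sample SD (n−1). Pairs with zero permutation SD (constant proportions,
empty categories) are flagged degenerate and scored 0, not dropped. The
Monte-Carlo estimator is validated against exhaustive enumeration of all
`n!` shuffles on ≤ 8-spot instances.

## Tumor zoning and surrounding spots

Both are pure functions of annotations and geometry; reruns are
bit-identical. Distance queries use a KD-tree, so the full pairwise matrix
is never materialized for large sections. Zones are monotone in the
distance to the nearest non-tumor spot by construction.

## Replicate consistency

Technical replicates are jointly embedded (per-sample gene z-scaling of the
normalized layer, shared PCA, k = 20 nearest neighbors) and clustered at
resolutions 1.0–2.0 in steps of 0.1. Per cluster and cell type, mean
estimated abundance is computed separately per replicate, and Pearson r
over the (cluster × type) means is reported per resolution. Per-sample
standardization before joint PCA stands in for explicit batch correction
and is recorded in the output. Note two legitimate inflation/deflation
sources when interpreting r: shared global per-type means raise r even for
uninformative clusterings, and with few cell types × clusters the estimate
has few degrees of freedom.

## Activities

**Pathway activity** restricts each pathway to its `top_n = 500` most
responsive genes (by responsiveness rank), z-scores expression per gene
across units, and sums weighted z-scores; with `scale=True` each pathway
column is z-scored across units for cross-sample comparison. The statistic
is linear in the weights.

**TF activity** is an analytic rank-based regulon score with a known null:
per spot, the N expressed (count > 0) genes are ranked; a target at rank r
contributes `Φ⁻¹(r/(N+1))`; the score is `Σ mode_i·q_i / √n` over the n
expressed targets (missing when n < 4; regulon edges restricted to
confidence grades A–C; likelihood weights treated as 1). Under exchangeable
expression the score is standard normal up to a small finite-N deflation
(population variance of the quantile grid ≈ 0.99 at N = 1,000), which the
calibration bands (mean ± 0.05, SD ∈ [0.95, 1.05] over 10,000 draws)
absorb. The score is symmetric in activation/repression via the target
modes.

**Module scores** bin genes into 24 equal-size mean-expression bins and,
per set gene, sample 100 control genes from its bin (seeded, with
replacement); the score is mean set expression minus mean control
expression. Degenerate case to be aware of: a gene set whose members occupy
bins containing only themselves gets controls equal to the set and scores
≈ 0 — planted-signal tests must keep set genes' means comparable to the
background.

**Clustering** z-scales activities per feature, zero-imputes missing values
(for the clustering only; all statistics elsewhere are missingness-aware),
and runs PCA (deterministic full SVD) → k-NN graph (k = 20) → seeded
Leiden modularity optimization at resolution 0.5. Leiden (leidenalg,
RBConfiguration) is used because no seedable Louvain implementation is
available; it optimizes the same modularity objective with a refinement
step, accepts an explicit seed, and the choice is recorded in cluster
parameters. Labels are renumbered by first occurrence for stability.

**ROC markers**: per feature × cluster, cluster-vs-rest AUC from the
Mann–Whitney construction (ties count ½) over defined scores, the fraction
of cluster spots with a defined score (≥ 25% required), and the difference
of group means on the supplied values. The fold-change-style threshold
(> 1) is applied to the mean difference of z-scaled activities, since
activities can be negative and a literal log2 ratio is undefined; pass
z-scaled activities to `roc_markers` to use it on that scale. AUC is
invariant under monotone transforms; markers require AUC ≥ 0.75.

**Correlation**: Pearson cross-correlation with pairwise deletion of
missing activities, or canonical correlation via the whitened
cross-covariance SVD (`Sxx^{-1/2} Sxy Syy^{-1/2}`), with near-null
directions of the covariances dropped (rcond 1e-10) — necessary because
proportion matrices are compositionally rank-deficient.

## Communication inference

**Ligand selection**: positive Wilcoxon markers (log2FC ≥ 0.5, BH p < 0.05)
of the pooled tumor+TME spots vs all others, intersected with the prior's
ligand list, and detected (count > 0) in ≥ 10% of interface spots in every
individual sample. **TME-TF selection**: ROC markers of the TME activity
cluster at AUC ≥ 0.75.

**Ligand→TF importance** replaces a multi-view random-forest model with a
deterministic, oracle-testable equivalent: per TF, activity is regressed by
ridge (closed form, α = 1) on two standardized blocks per ligand — 
expression at the spot (intraview) and the mean over spots within canonical
distance ≤ 2 (juxtaview; the ball includes the spot, and the synthetic
generator plants effects through the very same neighborhood function, so
generative and inferential definitions match by design). A ligand's raw
importance is the sum of its two absolute coefficients; importances are
z-scored across ligands per TF (hence exactly mean 0 / SD 1 per TF) and
averaged across samples. Associations with aggregated importance > 1 are
selected. Averaging across 4 samples shrinks the null SD to ½, which is
what makes the > 1 threshold selective (null exceedance ≈ 2–6% in the
default benchmark) while planted unit effects score ≈ 2–3.

**LR consensus**: for every ordered cluster pair and candidate LR pair,
three transparent component scores on the merged normalized layer — the
product of source-cluster ligand and target-cluster receptor means (s1),
the product of their cluster-specificity fractions (s2), and a permutation
p for s1 under joint cluster-label shuffles (n = 1,000, seeded). Each
component is ranked across all candidates; the aggregate rank is the mean
of the three normalized ranks in (0, 1], selected when < 0.01. Because the
permutation p has resolution 1/(n_perm+1), many candidates tie at the
minimum; ties in the p rank are broken by descending s1 so the component
stays informative (average-tie ranking would make the 0.01 threshold
unreachable for any candidate). A single-candidate table has aggregate rank
1 and can never be selected at the default threshold.

**Signaling networks**: for every selected (ligand, TF) association, each
of the ligand's selected receptors is connected to the TF by **all**
unit-weight shortest directed paths in the signed PPI graph (cap 50 paths
per pair, logged when hit), unioned and merged with the LR edges. Nodes are
typed ligand/receptor/intermediary/TF and annotated with mean normalized
TME-cluster expression where measured. Pairs with endpoints missing from
the PPI graph are reported "unmapped"; pairs with no path "unreachable" —
never silently dropped. Output formats: SIF and GraphML. Outputs are
associations, not causal claims.

## Differential expression and ORA

Per group vs rest: two-sided Wilcoxon rank-sum with exact enumeration of
all C(n1+n2, n1) rank splits (two-sided p = twice the smaller tail, capped
at 1) when both groups have ≤ 8 observations, and the tie-corrected,
continuity-corrected normal approximation otherwise; the two paths agree
within |Δp| ≤ 0.02 across a location-shift spot-check grid (the
approximation is loosest only in the uninformative p → 1 corner). Fold
changes are `log2((mean(expm1 x)+ε)/(mean(expm1 rest)+ε))` with ε = 1e-9;
ribosomal/mitochondrial genes (prefixes RPL/RPS/MT-) are removed before
testing; BH adjustment is across genes within group; default filters keep
positive markers with log2FC ≥ 0.25. The tumor-vs-non-tumor pre-filter for
inter-patient comparisons is available as a composable flag.

ORA is the one-sided hypergeometric upper tail `P[X ≥ k]` for the overlap
between a query and each gene set, both intersected with an explicit
background; sets need ≥ 5 background-present genes (preset 3 for the
inter-patient mode); BH across tested sets.

## Synthetic data: what it emulates, what it does not

The generator produces: hexagonal lattices with a connected tumor disk,
stromal annulus, epithelial/lamina background and optional immune
aggregates; per-region Dirichlet cell-type proportions (concentration 8 for
the dominant class, 1 elsewhere); negative-binomial counts from cell-type
signature mixtures (per-gene dispersion, default 10; ∞ = Poisson), scaled
to a target library size (default 5,000 UMIs, a realistic Visium depth);
technical replicates by re-drawing counts with optionally inflated
overdispersion; and planted ligand→TF couplings: a latent activity
`a_t(s) = Σ_l β_{l,t}·z(neighborhood ligand expression) + ε`,
ε ~ N(0, noise_sd²), tilts the TF's regulon-target means by
`exp(mode·a_t·τ)` with τ = 0.3 — strong enough to be recoverable through
the rank-based activity estimate, weak enough not to be trivial. All
generators are pure functions of (parameters, seed), and ground truth is
always serialized next to the dataset.

Not emulated: real gene identities, spatial autocorrelation of histology,
segmentation errors, batch structure beyond replicate noise, zero-inflation
beyond NB, or doublet/bleed-over artifacts. Passing tests therefore show
the statistics are correctly implemented and recover planted structure
under NB noise — not that they are robust to every artifact of real
sections.

## Benchmark and pipeline problem sizes

The standard study conditions, shared by the test suite and the acceptance
script: communication benchmark — 4 samples × 800 spots (40×40 lattice),
10 ligands, 5 TFs, 3 planted effects at standardized effect 1.0, activity
noise SD 1.0; LR benchmark — 1 planted pair among 200 decoys, 1,000
permutations; deconvolution — 5 types × 2,000 genes × 500 spots, library
5,000; TF null — 10,000 spots × 1,000 genes; pipeline — 2 patients × 2
technical replicates on a 55×55 lattice (1,513 spots each), ~640 genes,
with per-patient expression heterogeneity (60 genes × fold 2) so the
inter-patient differential-expression stage has true positives.

## Known limitations

- The NNLS stand-in ignores count overdispersion and spot-level covariates;
  its errors grow for collinear signatures.
- The importance model is linear; strongly non-additive ligand interactions
  would be attributed to the marginally most correlated ligands.
- The LR permutation p is granular at 1/(n_perm+1); the documented tie-break
  makes ranking stable but the p itself should not be over-interpreted.
- Leiden with a fixed seed is deterministic but resolution choices remain a
  modeling decision; cluster-to-compartment mapping in the pipeline uses
  annotation shares and can be ambiguous on sections without clear
  compartments.
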