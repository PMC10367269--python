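# Methods

`comornet` implements a comorbidity-network medicine workflow: from a
binary patient × diagnosis matrix it builds a weighted disease
co-occurrence network, partitions it into disease clusters, derives
subtype-discriminative comorbidity profiles, embeds the disease network
in a multiplex-heterogeneous disease–gene network, propagates profile
seeds by random walk with restart, and evaluates and prioritizes the
resulting gene rankings. All stages run on a bundled synthetic-data
generator whose planted structure makes recovery quantifiable.

## Comorbidity network

For every unordered pair of diseases with prevalence at or above a floor
(default 5 patients) the 2×2 co-occurrence table is tested with the
two-sided Fisher exact test. For totals up to 500 the p-value is computed
by exact integer enumeration of the conditional hypergeometric
distribution (numerators compared as integers, the final division
correctly rounded), above that by `scipy.stats.fisher_exact`. Strength of
association is the φ correlation — the Pearson correlation of the two
binary indicator vectors, `(ad − bc)/√((a+b)(c+d)(a+c)(b+d))`.

Edges are retained when the Benjamini–Hochberg-adjusted p falls below
α (default 10⁻⁴) *and* φ > 0. Because φ between rare and common diseases
is bounded well below 1, raw φ weights are hub-biased; each retained edge
is therefore rescaled by the mean retained-positive φ of its two endpoint
diseases. The default is the symmetric geometric form
`W_ij = φ_ij / √(m̄_i · m̄_j)`; an arithmetic-mean variant
(`φ_ij / ((m̄_i + m̄_j)/2)`) is available through the `scaling` flag, and
the means are computed over retained edges. Shortest-path metrics run on
the complementary score `S = max(W) − W`, so the strongest tie has length
zero: betweenness and closeness use S as distance, degree is unweighted,
strength sums W, and transitivity is the global clustering coefficient.
On disconnected graphs closeness switches to the harmonic variant and
says so in its output.

Clustering optimizes weighted modularity (weight W) with the Leiden
algorithm by default (`louvain` selects igraph's multilevel algorithm);
both are seeded and deterministic, cluster ids are relabelled by
decreasing size. Network comparison reports the edge Jaccard index on the
unioned node universe and DeltaCon similarity: node-affinity matrices
from fast belief propagation, `S = (I + ε²D − εA)⁻¹` with
`ε = 1/(1 + max degree)`, compared by Matusita root-euclidean distance,
similarity `1/(1 + d)`. Networks here are small, so the affinity matrices
are computed exactly (no block approximation).

Odds-ratio homogeneity between two patient strata uses the Breslow–Day
chi-square (optionally Tarone-corrected) around the Mantel–Haenszel
common OR. The implementation is in-package because the statsmodels
version divides by the vanishing quadratic coefficient when the common OR
is exactly 1; the linear limit (`ã = rs/n`) is handled explicitly. A
stratum table containing a zero cell receives +0.5 continuity (recorded
per pair); a zero margin skips the pair with a reason.

## Cohort profiles

MCA operates on the complete disjunctive indicator (presence and absence
both coded, so each disease contributes two columns), via SVD of the
standardized residuals of the correspondence matrix. Per-dimension
inertia percentages are reported against the total indicator-matrix
inertia, so they sum to 100 up to numerically-zero dimensions; constant
disease columns are dropped with a warning. Covariate variance
attribution regresses each dimension's patient coordinate on the
covariate (OLS slope test for numeric covariates, the equivalent one-way
F-test for categorical ones) and sums the inertia of dimensions with
p < 0.05. The number of dimensions tested defaults to min(50, rank).

The subtype classifier is elastic-net logistic regression
(scikit-learn saga solver, mixing 0.5, 20 log-spaced penalty strengths,
5-fold stratified CV scored by AUROC, all seeded). Forward selection
orders the nonzero-coefficient diseases by |coefficient|, grows the
feature set in steps of 10, scores each size by cross-validated AUROC of
an L1 logistic model, and keeps the smallest size within 0.002 of the
maximum — a plateau rule standing in for a visual elbow choice. Features
are the raw binary indicators (not standardized; all features share the
same scale). Signs of the final coefficients assign each selected disease
to one cohort.

## Cluster similarity contrasts

A patient's similarity to disease cluster DC is the Jaccard index of
their disease set (restricted, by default, to diseases covered by the
partition) with the cluster members. Cohorts are contrasted per cluster
with the two-sided Wilcoxon rank-sum test; the reported sign is the sign
of the rank-based location shift (equivalently of the Hodges–Lehmann
shift estimate, via `sign(U − n₁n₂/2)`), and `signed_logp = −log10(p)`
carries it. Raw and BH-adjusted p-values are both emitted, since either
convention is defensible for a per-contrast family of nine clusters.

## Heterogeneous network

Disease–gene associations keep rows with confidence strictly above the
threshold (default 0.29, the level at which one curated or several
experimental sources support a link in DisGeNET-style scoring),
collapsing duplicates to their maximum score. Gene layers can be
restricted to an expression whitelist — the union of whatever evidence
lists are supplied (proteome, tissue transcriptome, disease-state
transcriptome). Assembly takes the per-kind union of layer nodes as the
universes, requires disjoint disease/gene namespaces, normalizes each
layer's weights to a maximum of 1 (so no layer dominates transition
probabilities), and drops bipartite edges whose endpoints fell outside a
universe, counting them. Assembly is idempotent, and the two filters
commute.

## Random walk with restart (RWR-MH)

The supra-transition matrix is column-stochastic over all node replicas
(one per layer). From a replica, mass λ (default 0.5) crosses the node's
bipartite links when it has any — split proportionally to association
score and uniformly over the other multiplex's layers; of the remaining
within-network mass, 1 − δ steps inside the layer proportionally to
normalized edge weight and δ/(L−1) (δ default 0.5) jumps to each other
replica; a replica dangling in its layer hands its within-layer share to
the other replicas (self-loop when the multiplex has one layer). The
stationary vector solves `p = (1−r)·T·p + r·p₀` by power iteration
(restart r default 0.7, L1 tolerance 10⁻¹⁰, at most 1000 iterations,
non-convergence flagged); `r = 1` returns the restart vector exactly.
Seeds are disease profiles, uniform by default (coefficient weights
optional), spread over layer replicas by the per-layer restart weights τ
(uniform by default). Defaults r, δ, λ, τ follow the published RWR-MH
method, since no tuned values are available; all are exposed. A gene's
score `P` sums its replica probabilities (mean optional); ranks are dense,
descending, ties broken lexicographically for reproducibility.

Prioritization of profile A against profile B restricts to A's top 500
genes by probability and scores `G = P·|ΔR|` with `ΔR = R_B − R_A`. Genes
ranking worse under A are retained but flagged rather than dropped: |ΔR|
is sign-blind, and the flag preserves the direction for interpretation.

## Evaluation

Leave-one-out recovery: every disease with ≥ 2 bipartite gene links has
those links removed, the transition rebuilt, the walk seeded at the
disease alone, and the held-out genes scored against all genes of the
universe by AUROC, average precision (the step-wise AUC-PR form, stable
at tiny positive fractions) and median-rank ratio. AUROC from the ranking
equals the Mann–Whitney identity `U/(n₁n₂)`. The input network is never
mutated. Null baselines: a degree-preserving double-edge-swap rewiring of
the comorbidity layer (weights travel with their edge; 10·|E| attempted
swaps by default) and size-matched random seed profiles, summarized as
z-scores of the observed AUROC/AUC-PR.

Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hit
weight |t|^p, p default 1), permutation p-values from plain same-size
gene-set resampling (default 10,000 draws; the adaptive multilevel
scheme is unnecessary at these set sizes), NES = ES / mean |null ES| of
matching sign, and the leading edge at the running-sum extremum.
Enrichment of predictions is evaluated at several top-k cutoffs,
defaults k ∈ {50, 100, 200, 500}.

## Synthetic data

The generator emulates the statistical structure the analysis assumes.
Diseases receive log-uniform base prevalences (default range 0.01–0.2,
mimicking the heavy tail of aggregated diagnosis codes) and belong to one
of `n_clusters` clusters. Each patient samples one cluster (two with
probability 0.3), with membership odds of two designated clusters biased
by age group and sex (odds ×2) so covariate-stratified contrasts have
signal; diseases of the patient's clusters get their occurrence log-odds
raised by log(within_cluster_odds) (default ×6). Ten marker diseases
(half in cluster 0, half in cluster 1) carry a signed log(marker_odds)
shift (default ×3) by the patient's A/B subtype. Everything is
reproducible from a single seed, with an independent RNG stream per
stage.

Gene modules are disjoint random subsets of size n_genes/n_clusters
assigned up front. Each gene layer is the union of a preferential-
attachment subgraph inside every module and a sparser global
preferential-attachment background, with the degree budget split so the
configured mean degree holds. This construction was chosen over carving
modules out of a single scale-free graph after the fact: at desk scale
such graphs are so small-world that any posthoc "neighborhood" of
realistic module size has no network locality, which silently removes the
guilt-by-association structure the propagation stage is supposed to
exploit. Weighted layers carry integer weights 1–5, emulating
evidence-resource counts.

The bipartite map gives each disease `genes_per_disease` distinct genes
(default 8 — disease–gene databases are denser still, but 8 keeps the
400-gene desk universe from saturating), drawn from the disease's cluster
module with probability `module_locality`, else uniformly; confidence
scores are uniform on [0.05, 1], so the strict 0.29 filter retains
(1 − 0.29)/0.95 ≈ 74.7% of links. The phenotype-similarity layer connects
same-cluster pairs with probability `concordance` (default 0.5) and
cross-cluster pairs at a tenth of that. The ranked signature draws
standard-normal t-statistics and shifts the genes of cluster 0's module
by `signature_shift` (default 3).

### What the generator does not emulate

No diagnosis-code semantics, visit timing or longitudinal structure; no
shared genes between diseases of different clusters; no correlation
between disease prevalence and gene-set size; phenotype similarity is
cluster-driven rather than gene-driven. Passing tests therefore
demonstrate that the machinery recovers the structure it assumes, not
that real cohorts contain that structure.

One consequence is worth flagging. Because the FDR-filtered comorbidity
layer is nearly free of cross-cluster edges while the synthetic phenotype
layer carries its fixed cross-cluster edge share, adding the phenotype
layer *lowers* median leave-one-out recovery here (by ~0.03–0.06 AUROC)
instead of raising it as observed on real data, where phenotype
similarity contributes complementary, partly gene-driven information.
The layer-ablation ordering test documents this expected shortfall.

## Problem sizes and runtime choices

Test and acceptance runs use desk-scale conditions chosen once: null
error-control cohorts at 20,000 patients × 120 diseases; cluster-recovery
cohorts at the generator defaults (5,000 × 120, 6 clusters); classifier
cohorts at 3,000 × 60; heterogeneous-network experiments at 4,000
patients, 60 diseases, 400 genes in 4 layers, 8 genes per disease;
prioritization/GSEA chains at 2,500 × 40 with 200 genes. Permutation
counts are reduced in tests (hundreds to thousands) relative to the
10,000-draw default.

## Known limitations

- The exact Fisher path is quadratic in the margin support; cohorts are
  expected to have at most a few hundred diseases.
- MCA densifies the occurrence matrix; cohorts of ~10⁵ patients ×
  hundreds of diseases fit comfortably, but larger inputs would need a
  sparse randomized SVD.
- The power iteration rebuilds the full transition per leave-one-out
  disease; for universes beyond ~10⁴ nodes an incremental update would
  be preferable.
- Permutation GSEA p-values are bounded below by 1/(n_perm + 1).
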