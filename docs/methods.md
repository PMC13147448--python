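# Methods

## Data model

An `AbundanceTable` is a validated samples × taxa matrix (counts or
row-normalized relative abundances) at one taxonomic rank (ASV, genus,
order, phylum).  Rank aggregation sums columns under a taxonomy map, keeping
`unclassified` as an explicit column so row totals are conserved exactly.
Species-level analyses collapse replicate samples with the **mean
relative-abundance profile** per host species at one body site; pooling raw
counts before renormalizing is available as an option (`pooled=True`).  The
mean profile is the default because it weights replicate samples equally
instead of by sequencing depth.

Host phylogenies are rooted dendropy trees with non-negative branch lengths;
species names are matched to tips after underscore/space normalization and
case-folding, the convention of newick files.  Zero-length branches are
allowed (soft polytomies); negative lengths are rejected.

## Diversity

Shannon entropy is −Σ pᵢ ln pᵢ in nats (the base is a parameter), with
0·ln 0 = 0.  Beta diversity is Bray–Curtis on quantitative rows or binary
Jaccard on presence/absence (threshold strictly > 0).  No rarefaction is
applied by default; compositions are row-normalized instead.  Significance
letters for group comparisons come from a Kruskal–Wallis omnibus at α
followed, only when the omnibus rejects, by Dunn's rank-based pairwise
z-tests (tie-corrected) with Benjamini–Hochberg adjustment, rendered by the
insert-and-absorb compact-letter-display algorithm.  Gating on the omnibus
makes the family-wise chance of reporting more than one letter track α,
which the test suite verifies by simulation (400 null replicates, 3 groups
of 15).

## PERMANOVA and effect sizes

The distance matrix D is Gower-centered, G = −½ J (D∘D) J; total SS =
tr G.  Terms enter sequentially (Type-I): the SS of term k is
tr(G H_k) − tr(G H_{k−1}) with H the orthogonal projector of the cumulative
design (intercept first); the projector basis is computed by SVD so factor
dummies never need a reference level.  Pseudo-F uses the full-model
residual mean square.  p-values come from free permutation of observations
(rows/columns of G) with the +1 correction; restricted permutation is not
implemented.  The per-term effect size is the ANOVA-analogue partial
omega-squared applied to distance-based SS,

    ω²ₚ = (SS_t − df_t·MS_res) / (SS_t + (N − df_t)·MS_res),

which is bias-adjusted (≤ the uncorrected partial R²) and, in the balanced
one-factor Euclidean case, recovers the generating between-group variance
share (verified on synthetic data).  With Euclidean distances on 1-D data
the pseudo-F reproduces the classical ANOVA F exactly.

PCoA eigendecomposes G; negative eigenvalues (non-Euclidean metrics) are
counted and reported, not corrected, and proportions explained are taken on
the positive-eigenvalue sum.

## Phylosymbiosis detectors

**Mantel.** Pearson correlation of the aligned upper triangles; the null
jointly permutes rows/columns of the second matrix; one-sided ("greater")
by default because phylosymbiosis predicts positive association.  The
subsampled variant draws species uniformly **without replacement** at a
fixed size k (so sites with different species richness are comparable) and
runs an independent Mantel test per draw; subsampling and permutation
randomness come from independent `SeedSequence` sub-streams, so a single
full-size draw reproduces the plain Mantel test bit for bit.

**Dendrogram congruence.** The microbiota dendrogram is UPGMA
(average-linkage) on the chosen beta-diversity matrix — the standard choice
for phylosymbiosis dendrograms; ties merge the lexicographically smallest
representative pair, making the tree deterministic.  Both tree distances
operate on the sets of non-trivial clusters (internal-node leaf sets,
excluding singletons and the root):

* RF = |C₁ △ C₂|, normalized by 2(n−2), the maximum for two rooted trees
  whose non-trivial clusters are all distinct, so 1.0 means complete
  incongruence;
* MC = minimum total weight over perfect matchings of the two cluster lists
  (padded with empty sets), weight = symmetric difference of leaf sets,
  solved by the Hungarian algorithm (clusters are bitmasks for n ≤ 64, so
  the cost matrix is a vectorized popcount).  No tight closed-form maximum
  is standard, so nMC divides by the **maximum MC across the permutation
  null** by default (`null_mean` optional); the choice is recorded in the
  result.

The null relabels dendrogram tips by random bijections (the standard
phylosymbiosis null; regenerating random topologies is not used), and
p = (1 + #{null ≤ observed}) / (B + 1), one-sided toward congruence.  Host
polytomies are retained (they simply contribute fewer clusters).

### Known limitation: RF discreteness

Rooted RF takes few values and its random-label null concentrates at the
maximum (two random labelings almost never share a cluster).  The exact
permutation p-value is therefore valid but **conservative**: its realized
type-I error at nominal 0.05 is ≈ 0.02–0.03 for 32-species trees, and the
same ties cost power at moderate signal (≈ 0.87 rejection at φ = 0.75
where Mantel and nMC reach 0.99–1.0).  MC takes many more values, so its
p-values are close to uniform under the null.  The tests assert validity
(never anti-conservative) for both and near-uniformity for nMC only.

## Brownian-motion reconstruction

Per-taxon relative abundances are modeled as independent BM traits on the
shared host tree (a full matrix-normal multivariate fit is out of scope).
C[i,j] is the root-to-MRCA path length.  Root: GLS estimate with ML rate
σ̂² = r'C⁻¹r/n.  Internal nodes: the Gaussian conditional expectation
â + c'C⁻¹(y − â1), c[i] the node–tip shared path length — algebraically
identical to re-rooting at the node and re-estimating the GLS root, which
the tests verify, along with an external cross-check against
phytools::fastAnc.  The root also carries the empirical-Bayes posterior SD
√(σ̂²/(1ᵀC⁻¹1)) (flat root prior, σ² fixed at its ML value; no MCMC).

BM on a simplex is improper — node estimates can stray below zero — so
composition-level output clips at zero and renormalizes each node to sum
to 1, matching pie-chart semantics; traits are raw relative abundances for
that reason (a CLR transform would change the quantity being averaged).
Near-singular C (duplicate zero-length tips) gets a 1e-10 ridge with a
warning.

**Phylogenetic heritability.** y ~ N(â1, σ²_phylo C + σ²_e I) is fitted by
ML over the mixing proportion h in V(h) = h·C/t̄ + (1−h)·I (t̄ = mean tip
depth), using one eigendecomposition of C/t̄ so each likelihood evaluation
is O(n); h itself is the phylogeny-attributable variance share at the
average tip, reported as h² in percent.  On an ultrametric depth-scaled
tree this coincides with Pagel's λ.  Exact boundary fits (0% or 100%) are
preferred whenever their likelihood is at least as high as the interior
optimum.  Estimates are noisy below ~8 species (warned).

## Synthetic-data generator

`simulate_dataset` emulates the structure the detectors assume:

* **Host tree**: Yule (pure birth, rate 1), depth-scaled to 1, so the BM
  marginal variance equals the rate.
* **Latent species profiles**: per-taxon BM realization z_phylo
  (standardized to unit marginal variance) mixed with i.i.d. species noise
  as √φ·z_phylo + √(1−φ)·z_noise, so **φ is the proportion of heritable
  variance** (φ per site allowed; noise is independent per species × site,
  the BM component shared across sites).
* **Composition**: softmax of (taxon baseline, SD 1) + (site shift, SD 1) +
  2 × latent.  The latent amplitude of 2 on the logit scale makes a fully
  heritable community (φ = 1) clearly detectable (Mantel r > 0.6 at 32
  species) without saturating the simplex.
* **Counts**: Dirichlet-multinomial per sample — α = composition ×
  concentration (default 50, moderate 16S-like overdispersion; higher =
  closer to multinomial) — at depth 10,000 reads, 3 samples per
  species × site by default.

The generator does **not** emulate real-survey features such as uneven
sampling across species, primer/batch effects, taxon-specific detection
bias, or phylogenetic signal in taxon prevalence itself; passing the
recovery tests shows the detectors work under the generating model, not
that any particular real dataset has phylosymbiosis.

## Problem sizes and numerical choices

Simulation-based checks run at 32 species (the scale where the tree
distances are informative but runtimes stay in seconds): 500 replicates ×
199 permutations for type-I calibration, 200 replicates for power at
φ ∈ {0.75, 1}, 12 replicates per φ for dose–response monotonicity, and
10–20 replicates for heritability recovery on 64-tip trees.  Tolerances:
closed-form equalities at 1e-8; compositions and row sums at 1e-9; distance
round trips at 1e-12.  All randomness flows through `numpy` generators
seeded per stage (pipeline stages derive seeds from the master seed by a
stable hash, so any stage can be replayed in isolation and re-runs are
byte-identical; wall-clock timings are logged, never written into result
files).

## Design decisions that were genuinely open

* The alpha-diversity letter test is unspecified in typical figure legends;
  Kruskal–Wallis + Dunn + BH was chosen as the robust standard for
  microbiome box plots.
* Between-site correlation uses per-site mean profiles (not all sample
  pairs), matching how such heatmaps are usually computed.
* Sequential SS with user-controlled, prominently logged term order, since
  two-factor PERMANOVA reports rarely state the SS type.
* "Variation attributable to host phylogeny" is realized as BM + noise
  phylogenetic heritability; Pagel's λ / Blomberg's K variants are natural
  future flags.
* The congruence null permutes dendrogram tip labels rather than
  regenerating topologies; species subsampling is without replacement.
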