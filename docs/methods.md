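# Methods

## Problem setting

`paracong` analyses paired microbial communities — two communities
sampled from matched biological units, such as the endophyte community
of a parasitic plant organ and the community of its host's root or
rhizosphere — and asks two questions: *how congruent are the two
communities' compositional structures across samples?* and *which
taxonomic groups carry that congruence?* Around this core it provides
the standard supporting analyses used in amplicon surveys: alpha
diversity, co-occurrence networks with topological node roles, and a
microbe–metabolite association screen.

## Congruence: weighted UniFrac → PCoA → Procrustes

**Weighted UniFrac.** For samples A and B with relative abundance
vectors p, q over the leaves of a rooted phylogeny,

    d_raw(A, B)  = Σ_b  l_b · |P_b − Q_b|
    d_norm(A, B) = d_raw / Σ_b l_b · (P_b + Q_b),

where the sum runs over every edge b of the tree (each non-root node
contributes the edge above it), l_b is the branch length, and P_b is the
summed relative abundance of the leaves descending through b. The
normalized form is the default: it is bounded in [0, 1] and is the
common default in ecology toolkits; the raw form is available behind a
flag because upstream pipelines differ on this point. Tree leaves absent
from a table are treated as zero abundance; table taxa absent from the
tree are an error. Distances depend only on relative abundances, so
per-sample scaling is a no-op.

**PCoA.** Classical metric scaling via Gower double centering
B = −½·J·D⁽²⁾·J with J = I − 11ᵀ/n, eigendecomposition of B, and sample
scores eigenvector·√eigenvalue on the largest positive eigenvalues.
Negative eigenvalues (non-Euclidean distances) are dropped rather than
Cailliez/Lingoes-corrected — only the first two axes are consumed
downstream, and those are unaffected in practice. The proportion
explained uses the positive-eigenvalue sum as denominator. Each axis is
sign-flipped so its largest-magnitude score is positive, which makes
output files byte-reproducible across LAPACK builds. Eigenvalues below
1e-10 relative to the largest are treated as zero.

**Symmetric Procrustes and t₀.** Both configurations are
column-centered and scaled to unit Frobenius norm (the narrower matrix
is padded with zero columns); with singular values Σ of XᵀY,

    t₀ = trace Σ = √(1 − m²),   m² = 1 − (trace Σ)².

t₀ is 1 exactly when Y is a translated, uniformly scaled, orthogonally
transformed copy of X, and is symmetric in its arguments — the reason
the symmetric protocol was chosen over the asymmetric regression-style
variant. Reflections are allowed in the optimal rotation (no determinant
constraint), standard for symmetric Procrustes.

**PROTEST.** Significance by permuting the row order of Y;
p = (1 + #{t_perm ≥ t₀}) / (n_perm + 1) with the add-one estimator so p
is never 0. Default 999 permutations. Under independent Gaussian
configurations the empirical type-I error at α = 0.05 sits inside the
exact binomial interval (checked at 500 replicates in the test suite).

**Leave-one-out Δt.** The attribution procedure runs in four steps per
taxonomic group g at a chosen rank (phylum by default): remove g's taxa
from both tables; recompute weighted UniFrac on the remaining taxa
(relative abundances renormalize implicitly); recompute PCoA and the
congruence t₀′ on the first two axes; report Δt = t₀′ − t₀ against the
baseline computed under identical settings. Negative Δt means the group
supports congruence. Removal from both communities is the default; a
`side` option restricts removal to one community. Groups whose removal
would empty a sample are skipped and flagged. Baseline and loo runs use
the same axis count and UniFrac variant, so Δt is never an artifact of
changed settings.

## Synthetic paired communities

The generator provides ground truth for every downstream stage. Design:

* **Tree and taxonomy.** Yule (pure-birth) topology, exponential(1)
  branch lengths. Phyla are monophyletic: the clade hierarchy is cut at
  its deepest splits — starting from the root, the splittable clade
  nearest the root is repeatedly replaced by its children until
  `n_phyla` clades remain (ties broken by the seeded rng). Cutting
  clades means leave-one-out removal corresponds to pruning subtrees,
  as with real phyla.
* **Counts.** Per sample j, shared factors f_j ~ N(0, I_K) and
  community-specific factors g_j^A, g_j^B ~ N(0, I_K); per taxon i,
  baseline b_i ~ N(0, 1) and loadings w_i ~ N(0, 1/K). Log-propensity
  η_ij^C = b_i + w_i·(λ f_j + (1−λ) g_j^C) + ε with ε ~ N(0, σ²);
  relative abundances are the softmax of η over taxa and counts are
  Multinomial(N, p_j). λ ∈ [0, 1] sets the cross-community coupling.
* **Carrier phylum.** When set, taxa outside the carrier have their
  shared-factor term replaced by the community-specific term in
  community B only: η_ij^B = b_i + (1−λ)·w_i·g_j^B + ε. Only carrier
  taxa then transmit the shared signal, so removing the carrier (and
  only the carrier) should erase congruence — the planted truth the
  Δt statistic must recover.
* **Metabolites.** Coupled metabolite m tracks α_m·log(relative
  abundance of its taxon + 1e-6) plus N(0, met_noise_sd) noise, with
  |α_m| ~ U(α_min, α_max) and a random sign; uncoupled metabolites are
  N(0, 1). Intensities are shifted per metabolite to be non-negative — a
  monotone shift, invisible to rank statistics.

**Defaults** are the conditions of the recovery scenario exercised
throughout the tests: 30 taxa, 5 phyla, 20 samples, λ = 0.9, σ = 0.5,
N = 5,000 reads, 30 metabolites with 5 couplings at |α| ∈ [1.5, 2] and
metabolite noise sd 0.5. The latent dimension defaults to **K = 1** —
a single shared gradient, the smallest model in which congruence and its
leave-one-out attribution are identifiable from the two retained
ordination axes. Larger K spreads the planted signal over more
directions than two axes can represent, so the recovery property
degrades (the strength of the effect, not its direction, depends on K).
All randomness flows from one integer seed through per-operation
substreams (tree, taxonomy, tables, metabolites), so a scenario is a
pure function of its config.

**What the generator does not emulate:** sequencing error, chimeras and
OTU-clustering artifacts; over-dispersion beyond multinomial sampling;
spatial or temporal autocorrelation between samples; realistic taxon
abundance distributions (baselines are log-normal via b_i, not fitted to
any survey); rhizosphere chemistry. Passing tests therefore demonstrate
the statistical machinery recovers planted structure under a clean
compositional model — not that any particular real system has such
structure.

## Alpha diversity and rarefaction

Chao1 = S_obs + F1²/(2·F2) when doubletons exist, else the
bias-corrected S_obs + F1(F1−1)/2; it needs integer counts (singleton
and doubleton tallies), so non-integer tables are rejected.
Gini-Simpson 1 − Σ p_i². Pielou evenness uses natural-log Shannon
entropy divided by ln S_obs; the ratio makes the log base irrelevant,
and samples with a single taxon get NaN rather than a division by zero.
Rarefaction draws a multivariate hypergeometric sample per community
(subsampling without replacement to exact depth); samples below depth
are dropped with a warning.

## Co-occurrence networks

Spearman rank correlation of relative abundances (midranks for ties) is
the default edge statistic; a basic SparCC estimator (log-ratio
variation matrix, sparsity approximation for component variances, up to
10 exclusion iterations of the most correlated pair above |ρ| = 0.1) is
available for users who prefer a composition-aware measure. Edge
significance is an empirical pseudo-p from null datasets built by
independently permuting each taxon's values across samples — margins
preserved, all pairwise association destroyed — with the add-one
estimator over 1,000 null datasets by default. Edges are kept iff
|r| > 0.6 AND p < 0.05, both strict; isolated nodes are retained.

Modules come from Clauset–Newman–Moore greedy modularity maximization on
the unweighted graph (edge presence only; signs and weights are not used
in the module analysis). Nodes are relabelled in sorted order before
agglomeration so heap tie-breaks are reproducible. Node roles follow the
participation framework: within-module degree z-score Zi (0 when the
module's within-degree sd is 0) and participation coefficient
Pi = 1 − Σ_m (k_i,m/k_i)² (0 for isolated nodes), with the conventional
thresholds Zi ≥ 2.5 and Pi ≥ 0.62 — both inclusive — separating
peripherals, connectors, module hubs and network hubs. Both thresholds
are flags, since they are conventions rather than estimates. Global
attributes: average degree avgK = 2E/N and average path distance GD over
connected ordered pairs, with the unreachable-pair count reported
explicitly rather than silently folded in.

## Microbe–metabolite screen

Spearman ρ with the Fisher-transform Z-test,
z = arctanh(r)·√(n−3), two-sided normal p. |r| is clamped to 1 − 1e-15
before arctanh so perfect monotone pairs yield p numerically 0 rather
than an overflow. The Fisher-transform variant was chosen over
r·√(n−1) z-scores because it is the standard large-sample test for rank
correlations and is accurate enough at n ≥ 10 (the test suite checks it
against an exact permutation p within a factor of two). Flags: "**" for
p < 0.01, "*" for p < 0.05, raw p by default — Benjamini–Hochberg is
available behind a flag but off by default, matching the usual practice
of starring raw p in correlation heatmaps. Aggregation to a higher rank
sums counts within groups before converting to relative abundance.

The differential-metabolite filter consumes externally computed OPLS-DA
statistics and keeps rows with VIP > 1 (strict), p < 0.05 (strict) and
|log2FC| ≥ 1 (inclusive) — the boundary semantics are deliberate and
covered by tests; VIP fitting itself is out of scope.

## Numerical choices and degenerate inputs

* DistanceMatrix symmetrizes after verifying symmetry within 1e-10 and
  clips negative rounding residue at 0.
* t₀ is clipped at 1.0 to absorb SVD rounding at exact
  superimposability; t₀ = √(1 − m²) holds to 1e-10.
* Procrustes requires ≥ 3 samples and errors on all-identical rows
  (zero Frobenius norm after centering).
* Correlation matrices exclude zero-variance taxa with a warning;
  the association screen skips constant features (NaN cells) instead of
  erroring, since one flat metabolite should not kill a screen.
* All-zero samples are an error everywhere relative abundances are
  needed, naming the offending sample.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on synthetic data
at the generator's default scale (30 taxa / 20 samples / 5,000 reads),
with 100 random instances for the UniFrac oracle comparison, 1,000
configurations for Procrustes exactness, 500 replicates each for the
PROTEST and association calibrations, and 20 replicate scenarios for the
Δt-recovery check. These sizes give stable rates (binomial 99% bounds)
while keeping a full run in the low tens of seconds.

## Known limitations

* The SparCC implementation is the basic estimator, not the full
  iterative resampling procedure of the original program; it is provided
  as an alternative correlation engine, and the default remains
  Spearman.
* Negative-eigenvalue mass in PCoA is discarded, so proportions
  explained are relative to the positive spectrum only.
* The Δt-recovery property is statistical, not certain: in roughly 1 in
  20 scenarios at the default conditions the carrier phylum is negative
  but not the unique minimum, driven by seeds where the carrier's
  abundant taxa draw small loadings.
* GD is a mean over connected pairs; comparing GD across networks with
  very different connectivity can mislead — the unreachable-pair count
  is reported for that reason.
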