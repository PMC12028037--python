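# Methods

This note documents the statistical procedures implemented in `comstab`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
results.

## Diversity and ordination

**Shannon index.** H = −Σ pᵢ ln pᵢ over taxa with pᵢ > 0, natural log by
default (`base` flag available); proportions are formed after filtering, so a
subnormal count that underflows to zero probability contributes nothing.

**Bray–Curtis.** d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), delegated to
`scipy.spatial.distance.pdist`. Defined on relative abundances in the
pipeline.

**PCoA.** Gower double-centering B = −J(D∘D)J/2 followed by a symmetric
eigendecomposition; coordinates are eigenvectors scaled by √λ for positive
eigenvalues only. `pct_explained` is relative to the **sum of positive
eigenvalues**; negative eigenvalues (Bray–Curtis is not Euclidean) are
dropped without correction. This is the least-assumption choice when no
correction method is stated; a Lingoes-style correction was considered and
deliberately left out to keep the axis percentages comparable with the most
common toolchain output.

**ANOSIM.** All pairwise distances are converted to midranks;
R = (r̄_between − r̄_within)/(N(N−1)/4). The p-value is one-sided (large R)
with the add-one estimator p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm), which
can never return p = 0. `n_perm="exhaustive"` enumerates every distinct
label arrangement and returns the exact proportion. Note the test is
slightly conservative at very small group sizes because the permutation
space is coarse (with 4+4 samples only 35 distinct partitions exist).

**Mantel.** Correlation (Pearson or Spearman) of the upper triangles, with
joint row/column permutation of the second matrix; two-sided by default,
add-one estimator, exhaustive option as above.

**Geodesic distances.** The inverse geodesic problem on the WGS84 ellipsoid
is solved with Vincenty's iterative formulae, implemented directly
(`comstab.geodesic`). Agreement with a high-precision reference
implementation is better than 0.1 mm on intercontinental test pairs; nearly
antipodal pairs, where the classical iteration can stall, fall back to a
damped iteration and emit a warning.

## Co-occurrence networks

Networks are built per sample group (e.g. per soil type), on that group's
samples only.

**Input table.** Spearman correlations are computed on the (filtered)
**count** table, not the row-normalized one. This matters: ranks make
sequencing depth a weak nuisance, while row-normalizing first lets
compositional closure cancel exactly the shared variation of dominant
co-varying taxa — the signal a co-occurrence network is supposed to detect.
Relative abundances are used wherever abundance *weights* are needed
(node abundance, cohesion, robustness weights).

**Taxon filter.** Default prevalence ≥ 0.2 of samples, no mean-abundance
floor. Correlation p-values for near-absent taxa are meaningless; the
threshold is configurable and recorded in the run manifest.

**Edges.** Pairwise Spearman with midranks; p from the t-approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df (the behavior of the standard correlation-
matrix toolchain); |ρ| = 1 pairs get p = 0 (below representable tail mass).
An edge is kept when |ρ| ≥ 0.6 and the Benjamini–Hochberg-adjusted p < 0.05.
These thresholds are a documented default in line with common practice in
microbiome co-occurrence studies, not a claim about any particular dataset;
both are configurable, as is `correction="none"`. Zero-variance taxa are
excluded and logged. Isolated nodes are dropped by default.

**Topology.** Average degree 2l/n and density 2l/(n(n−1)) satisfy
density = average_degree/(n−1) identically, which the test suite asserts on
random graphs. Module detection is Louvain on |ρ|-weighted edges with
resolution 1.0 and a fixed seed; the graph is relabelled to integer nodes
first so that the partition is identical across processes (Python string
hashing is randomized per process and changes set-iteration order inside
Louvain). Modularity Q = Σ_c [e_c/W − γ(a_c/2W)²] is computed by a
deterministic summation in edge order. Module hubs are ranked by the
within-module degree z-score Zᵢ (ties: total degree, then node id);
singleton modules score −∞.

## Cohesion (complexity)

Per-taxon connectedness is the mean of the *retained* positive (resp.
negative) correlations with other taxa; by default the retained set is
exactly the network's edge set (`corr_source="network_edges"`), with
`"all_significant"` (raw p < α, no |ρ| floor) as an alternative. Cohesion of
a sample is the abundance-weighted sum of connectedness; total cohesion is
positive cohesion plus the magnitude of negative cohesion. Because
abundances sum to 1 and |connectedness| ≤ 1, all cohesion values are bounded
by 1. A null-model-corrected connectedness (subtracting the expected
correlation under independent per-taxon shuffles) is available behind
`null_model_correction` in the pipeline configuration but is off by default.

## Robustness (stability)

A perturbation removes either ⌊f·n⌋ uniformly random nodes (default f = 0.5,
999 iterations in the pipeline default; the acceptance script uses 499) or
the top-k module hubs (default k = 5, deterministic, one iteration).
Secondary extinctions then iterate to a fixed point: a remaining species
goes extinct when it has no remaining network edges **or** its
abundance-weighted mean association strength over the remaining community,
Σ_{j≠i} bⱼsᵢⱼ / Σ_{j≠i} bⱼ, is ≤ 0. The robustness score is the mean over
iterations of (remaining species)/(initial network size).

Association strength sᵢⱼ is the Pearson correlation computed on the same
abundance table the network was inferred from, while bⱼ is relative
abundance. Correlating row-normalized abundances here instead would make the
score collapse whenever a co-varying block dominates a community: closure
turns the block's associations negative and triggers a global extinction
cascade regardless of network structure. With the chosen convention the
score responds to the community's actual co-occurrence structure.

**Per-sample stability.** Downstream analyses (driver screening, PLS-PM)
need stability as a per-sample variable, which the group-level score is not.
The package defines it as the robustness of the subnetwork induced by the
taxa present (abundance > 0) in that sample, with the same protocol and
parameters, independent child seeds per sample, and score 0 for samples
whose induced subnetwork has no edges. This definition is explicit,
isolated in one function (`cohesion.per_sample_stability`), and easily
replaced.

## Environmental drivers

Spearman ρ and p for every (environmental variable, response) pair, with
stars (*, **, ***) at p < 0.05/0.01/0.001. Stars follow the raw p by
default — matching the convention of published correlation heatmaps — and
the Benjamini–Hochberg-adjusted q when `correction="BH"` (recommended for
new analyses). Constant variables yield flagged, not-computable cells. C:N
and C:P are computed as TC/TN and TC/TP when absent from the input matrix.
Simple linear regression is ordinary least squares with a two-sided t-test
on the slope.

## PLS path modeling

The structural model is a DAG over latent variables, each measured by a
reflective (mode A) block of manifest variables. Estimation is the classical
Lohmöller alternation: standardize manifests; initialize outer weights
equal; then iterate outer estimation (scores = weighted block sums,
restandardized), inner estimation (centroid scheme by default: adjacent
scores weighted by the sign of their correlation; factorial and path schemes
available), and mode-A outer weight update (manifest–inner-proxy
covariances) until the largest change in normalized weights falls below
1e−7 (max 300 iterations; non-convergence raises, carrying the last delta).
Path coefficients are OLS of each endogenous latent score on its
predecessors (with a condition-number guard against collinear predecessors);
R² per endogenous latent; goodness of fit √(mean communality × mean R²).

Numerical conventions: latent scores use population (1/n) standardization
(Lohmöller convention); the PLS sign indeterminacy is resolved by orienting
every latent so its mean loading is positive. Effects decompose exactly:
with a strictly lower-triangular coefficient matrix B, total = B + B² + … +
B^(L−1), direct = B, indirect = total − direct.

Significance is assessed by a nonparametric bootstrap (resample samples with
replacement, refit, percentile CI and two-sided percentile p; non-convergent
resamples are dropped and counted, > 20% is an error). The bootstrap is the
package's choice for path significance; analytic standard errors are not
provided.

The pipeline's default ("paper-shaped") model uses seven latents — soil
properties (ORP, pH, temperature, salinity, clay/silt/sand), nutrients
(TOC, TC, TIC, TS, TN, TP, PO₄³⁻, SO₄²⁻, NO₂⁻-N, NO₃⁻-N, NH₄⁺-N),
geographic distance (per-sample mean geodesic distance to all other
samples), alpha diversity (Shannon), beta diversity (PCoA axes 1–2) — with
arrows from the first three into both diversities and from all five into
complexity (total cohesion) and stability (per-sample robustness). How beta
diversity, distance, complexity and stability enter as per-sample manifests
is not canonical; these choices are explicit and configurable.

## Synthetic data generator

The generator produces the package's study conditions: two soil-type groups
of 30 samples over 60 taxa in five taxon classes.

* **Dominance.** Clay loam concentrates 55/20/10/9/6% of abundance on the
  five classes (strong single-class dominance, hence lower alpha
  diversity); sandy is nearly even (25/23/20/17/15%). Within a class,
  per-taxon base abundances are log-normal (σ = 1).
* **Correlation blocks.** Rank correlation is injected by a Gaussian
  copula: block taxa share a latent factor with equicorrelation
  r = 2 sin(πρ_s/6), so the copula's Spearman correlation equals the target
  ρ_s while each taxon keeps its own negative-binomial marginal
  (dispersion k = 5, depth 10,000). Negative blocks alternate loading
  signs (+−+−…), because k > 2 taxa cannot be mutually negatively
  equicorrelated beyond −1/(k−1). Blocks are group-specific: clay loam is
  cooperative (positive blocks of 12 taxa at ρ 0.75 in its dominant class,
  12 at 0.75 and 12 at 0.70 in mid classes, one small negative block of 6
  at 0.60); sandy carries one positive block (6 at 0.60) and a substantial
  competitive block (10 at 0.75, alternating signs). The competitive sandy
  structure mirrors the field observation that fungal associations are
  relatively more positive and cooperative in clay loams, and it is what
  makes the sandy network both less cohesive and less robust: its
  negative-block members fail the weighted-association survival rule early.
* **Library sizes.** A shared per-sample log-normal depth factor
  (σ = 0.25) couples all taxa of a sample weakly and positively, as real
  amplicon libraries do. A multinomial count model (fixed depth per sample)
  is available behind `count_model="multinomial"`.
* **Environment.** Latent scores are drawn along a DAG: exogenous latents
  standard normal, endogenous latents path-weighted parent sums plus just
  enough Gaussian noise to stay unit variance — so a single-parent path
  coefficient equals the implied latent correlation. Manifests are
  loading × latent + noise with loading 0.8 and, by default, noise sd
  √(1−loading²), i.e. unit-variance manifests; an affine per-variable
  (mean, scale) map produces unit-ful output. The hidden latent scores are
  returned for recovery testing. Recovery note: mode-A composites built
  from seven manifests per latent (the size of the soil-properties block)
  attenuate structural paths by ≈ 7%, which keeps mean estimates within
  ±0.05 of the generating coefficients at n = 500; with many fewer
  indicators per block the attenuation is materially larger and should not
  be read as estimator failure.
* **Coordinates.** Site centers (three mangrove sites on the southern
  China coast) plus uniform jitter of ≤ 200 m per axis.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: taxonomic structure beyond opaque classes;
phylogenetic signal; zero-inflation beyond what the negative binomial
produces; environmental gradients that *cause* community composition (the
environmental matrix is generated from its own latent model, independent of
the counts, so community–environment Mantel correlations are null by
construction); temporal or spatial autocorrelation within sites; and true
compositional sampling at fixed depth (unless the multinomial model is
chosen).

## Problem sizes and determinism

The default test-suite and acceptance scales — 30 samples per group, 60
taxa, 199–999 removal iterations, 499 bootstrap resamples, 999
permutations — were chosen so that the full suite runs in a few minutes on a
single core while keeping Monte-Carlo noise well below the effect sizes the
tests assert; all are configurable upward. Every stochastic stage takes an
explicit seed, all generators are pure functions of (spec, seed), and two
runs of the same configuration produce byte-identical output files, which
the test suite verifies by hashing.

## Known limitations

* Spearman co-occurrence networks are not compositionality-aware; SparCC or
  SPIEC-EASI style inference is out of scope by design.
* The robustness score depends on the stated extinction rule; other rules
  (e.g. pure topological percolation) give different absolute values.
* PLS-PM here covers reflective blocks only; formative measurement and
  covariance-based SEM are out of scope.
* The per-sample stability definition is a package convention (see above),
  not a community standard.
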