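# Methods

This note documents the statistical procedures implemented in `micronet`,
the conventions chosen where several are in circulation, and what the
synthetic-data experiments do and do not establish.

## Correlation screen

Spearman's ρ is computed with average (tie-corrected) ranks for every OTU
pair within a sample group; two-sided p-values use the t approximation
t = ρ √((n−2)/(1−ρ²)) with n − 2 degrees of freedom, the standard for rank
correlation at the sample sizes typical of field surveys (n ≈ 10). A
permutation option exists (`p_method="permutation"`): exact enumeration for
n ≤ 7 samples, seeded Monte Carlo (9 999 permutations) above that. OTUs
with constant profiles have no defined correlation; they are recorded as
NA with p = 1, excluded from the multiple-testing pool, and can never form
an edge.

False discovery control uses Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) on
λ = 0.05, …, 0.95, smoothed by a cubic polynomial and read off at λ = 0.95;
q_i = min_{p_j ≥ p_i} π₀ m p_j / rank(p_j). If the smoother leaves (0, 1]
the estimate falls back to π₀ = 1, which reduces q-values to
Benjamini–Hochberg (also available directly via `method="bh"`). Q-values
are computed over all testable (non-constant) pairs, not only pairs passing
p < 0.01; the alternative pooling is a config switch away but is not the
default because conditioning the FDR pool on the p threshold changes the
meaning of q.

Edges require |ρ| ≥ 0.9 AND p < 0.01 AND q < 0.05 (defaults in
`PipelineConfig`; environment–OTU edges use |ρ| ≥ 0.6, p < 0.05,
uncorrected). Edge orientation is canonical (lexicographically smaller OTU
first); nodes without a surviving edge are dropped, so the graph never
contains isolated nodes.

## Topological indices and conventions

- **Modularity (MD)** — Newman's Q of the fast-greedy
  (Clauset–Newman–Moore) partition, computed on the unweighted, sign-blind
  graph. The merge path is deterministic given the edge set; module ids are
  assigned in decreasing size order.
- **Clustering coefficient (CC)** — mean local clustering over nodes of
  degree ≥ 2 (the igraph average-local-transitivity convention). The
  alternative that counts degree-<2 nodes as 0 is available as
  `cc_mode="count_zeros"`. The exclusion convention is the default because
  the published random-network clustering values of the reference study
  (e.g. 0.008 at N = 329, E = 436, where ≈ 26% of G(n, m) nodes have
  degree < 2) are reproduced only under it — those values were produced
  with igraph.
- **APL / ND** — mean and maximum shortest-path length over *connected*
  ordered pairs; disconnected pairs are excluded rather than treated as
  infinite or the graph restricted to its largest component. Thresholded
  correlation networks are routinely disconnected, and per-pair averaging
  is the common toolkit default.
- **AD / GD** — closed forms 2E/N and 2E/(N(N−1)). In the reference
  study's summary table every printed density/degree cell matches these
  identities except the two bacterioplankton average degrees (printed
  2.63 and 8.21 vs 2E/N = 2.65 and 8.18); the discrepancy is unexplained
  and those two cells are excluded from the identity checks rather than
  guessed at.

Degree-distribution fitting follows the R²-on-log-log-axes tradition:
least squares of log P(k) on {log k}, {k}, {log k, k} for the power-law,
exponential and truncated power-law models, selecting the model with
maximal R². Because the truncated model nests both others, its R² is never
smaller — model selection therefore asks whether the *additional* term is
doing work, which the generative recovery test probes (degrees drawn from
k^(−1.5) e^(−k/20) select the truncated model in ≥ 90% of runs).
Maximum-likelihood fitting is deliberately not the default: the reference
values being mirrored are R²-based.

## Null models and group comparison

The default ensemble is G(n, m): uniform simple graphs with exactly the
empirical node and edge counts. This choice follows the observation that
the published random-network clustering equals the empirical density in
every row of the reference table — the signature of a uniform G(n, m) null
rather than a degree-preserving one. Degree-preserving double-edge-swap
rewiring (10E swaps per replicate) is available as
`model="degree_preserving_swap"`. Fast-greedy modules are re-detected in
every replicate when MD is requested. Z-tests compare an observed index to
the ensemble mean and SD, with a degeneracy flag when the SD is 0.

The reference study reports Student t-tests between the two zones'
indices, but a single network per zone yields one number per index, so the
procedure cannot be taken literally. `compare_zones` interprets it as a
bootstrap: each zone's samples (columns) are resampled with replacement,
the full pipeline is rebuilt per resample, and the observed index
difference is tested against the combined bootstrap spread,
z = (I₁ − I₂)/√(sd₁² + sd₂²), two-sided normal. The textbook alternative —
a Welch t-test between the two bootstrap distributions — is kept as
`method="welch"` but is anti-conservative by construction (its standard
error shrinks with the number of bootstrap replicates, which only refine
an SD estimate).

**Known limitation.** Resampling 10 columns with replacement leaves ~6.5
distinct samples per replicate; at that effective n the |ρ| ≥ 0.9 screen
passes far more often, so bootstrap networks are denser than the observed
one and the AD spread is inflated. In calibration experiments with
identical zones the z-test rejects at ≈ 0.02–0.10 for CC and MD but can be
over-conservative for AD, and its power for AD contrasts is limited. The
directional contrast (more edges and higher AD in a strong-structure zone)
is robust; calibrated per-index significance for degree-based indices at
n = 10 is not something this resampling scheme can fully deliver.

## O/R co-occurrence ratios

For a given edge sign, the observed incidence O(a, b) is the percentage of
same-sign edges joining phyla a and b (intra-phylum uses a = b; incidences
sum to 100 per sign). The random incidence R(a, b) is the mean incidence
over G(n, m) networks drawn on the same labelled node set with the same
number of same-sign edges — for that ensemble R converges to the phylum
pair-count fraction, which the tests exploit as an exact combinatorial
oracle (a 6-node two-phylum fixture with all edges intra-phylum has
R = 20%, hence O/R → 5). Empirical significance uses the add-one
estimator p = (1 + #{replicate ≥ O})/(n + 1) for O/R ≥ 1, mirrored below 1,
so p is never exactly 0. Ratios are reported NA where R = 0. When a sign
has no observed edges the whole table is flagged undefined rather than
zero-filled. Proteobacteria are conventionally analysed at class level
(Alpha/Beta/Gamma); the generator's phylum labels already follow that
resolution.

## Node roles

Zi standardizes the node's within-module link count against its module's
within-degree distribution using the population SD (the original
definition); Zi = 0 by convention when that SD is 0 (the alternative is
±∞). Pi = 1 − Σ_s (k_is/k_i)². Roles split at Zi = 2.5 and Pi = 0.62 with
boundaries inclusive on the low side: peripheral (≤, ≤), connector (≤, >),
module hub (>, ≤), network hub (>, >). Roles are computed on the
sign-blind graph, consistent with module detection.

## Module eigengenes and environment

The eigengene of a module is the first right singular vector of the
member OTU × sample matrix after standardizing each member profile to mean
0, SD 1 across samples (the WGCNA construction; standardization is the
default and a deliberate choice — unstandardized profiles let one abundant
OTU dominate). The sign is fixed so the eigengene correlates non-negatively
with the module's mean standardized profile. Variance explained is
s₁²/Σs². Single-member modules return the standardized profile, flagged;
modules below `min_module_size` (default 4, matching the convention of
dropping sub-4-node modules from reporting) are skipped in the
eigengene–environment analysis. Eigengene–environment association uses
Spearman ρ with p < 0.05, uncorrected, with |ρ| exported as line weight
for plotting.

## Synthetic data generator

The generator emulates the sampling design the pipeline targets: two zones
of 10 water samples, a configurable number of OTUs (default 120, four
planted modules of 20 plus 40 background OTUs), multinomial sequencing
counts at depth 20 000, six environmental analogues (TN, TP, NH₄, NO₂,
DOC, pH) drawn standard-normal per zone.

Per zone and module, a latent factor f_m is drawn per sample (standard
normal, or set equal to an environmental variable when `env_link` ties the
module to it). Member OTU i gets latent log-abundance
λ s_i f_m + ε, with λ the zone's loading strength, s_i = ±1 (25% negative
by default, producing co-exclusion edges) and ε ~ N(0, noise_sd²)
(default 0.3); background OTUs get pure noise. A per-sample softmax yields
proportions and a multinomial draw yields counts, so columns sum exactly
to the depth and the data are compositional like real libraries. The
latent within-module correlation is λ²/(λ² + σ²): ≈ 0.91 at the default
strong loading 0.95, ≈ 0.73 at the weak loading 0.5, 0 at loading 0. All
randomness flows from one seed through named sub-streams, so datasets are
bit-reproducible.

What the generator does **not** emulate: heavy-tailed abundance
distributions, taxon-specific sequencing biases, rarefaction artifacts,
true ecological dynamics, or read-level errors. Two behaviours of the
compositional closure are worth knowing when interpreting validation
results. First, the shared softmax denominator adds a weak positive common
component to all proportions, which attenuates negative correlations and
gives background OTUs mild mutual correlation. Second, with the
within-module correlation (0.91) sitting essentially at the edge threshold
(0.9), only about half of within-module pairs become edges at n = 10;
detected modules are then denser sub-blocks of the planted ones (often
split along loading sign), and fast-greedy modularity of the detected
partition exceeds that of the planted partition. Consequently planted-
module recovery at the default conditions reaches ARI ≥ 0.8 in roughly
half the seeds rather than almost always — a property of the planted
design interacting with the hard threshold, not of the detection
implementation, which matches brute-force and independent-library results
exactly. Passing tests on this generator establish internal correctness
of each statistic and the expected qualitative contrasts; they do not
establish performance on real amplicon data.

## Problem sizes and numerical choices

Validation experiments run at desk scale: 10–50 simulation seeds,
80–120 OTUs, 20 bootstrap replicates per zone comparison, 200–2000
random-network replicates (1000 is the reporting default; the ensemble
mean clustering at N = 329, E = 436 has Monte-Carlo SE ≈ 1.7 × 10⁻⁴ at
1000 replicates, well inside 3-decimal rounding). Brute-force oracle
comparisons use 1e−12 absolute tolerance. Ties in q-value computation are
resolved by stable sorting (equal p ⇒ equal q). Degenerate inputs raise
informative errors early: empty graphs, zero sample totals (naming the
sample), constant environmental variables (skipped with a warning),
partitions not covering the graph.
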