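# micronet

Co-occurrence network analysis for microbial community OTU tables.

Microbial ecologists routinely summarize amplicon surveys (16S
bacterioplankton, 18S microeukaryotes) as **co-occurrence networks**: nodes
are OTUs, and an edge links two OTUs whose relative abundances are strongly
and significantly rank-correlated across samples — positive edges suggesting
co-occurrence, negative edges co-exclusion. `micronet` implements that
workflow end to end for studies that contrast sample groups (e.g. lake zones
with different nutrient loadings), together with the downstream statistics
used to interpret such networks, and a synthetic-data generator with planted
module structure so every stage can be validated without sequencing data.

## The method

Starting from an OTU × sample count table, per group of samples:

1. **Prevalence filter** — keep OTUs present (count > 0) in ≥ 8 of the
   group's samples; convert counts to relative abundances, closing to 1
   within each kingdom block (16S and 18S depths are not comparable).
2. **Correlation screen** — all-pairs Spearman ρ with two-sided p-values
   (t approximation, n − 2 df) and Storey q-values (smoother π₀ estimate).
   An edge is kept iff |ρ| ≥ 0.9, p < 0.01 and q < 0.05.
3. **Topology** — fast-greedy (Clauset–Newman–Moore) modularity
   maximization partitions the sign-blind graph into modules; the network is
   summarized by modularity (MD), average local clustering (CC), average
   path length (APL), diameter (ND), average degree (AD = 2E/N) and graph
   density (GD = 2E/(N(N−1))). Degree distributions are fitted on log-log
   axes under power-law, exponential and truncated power-law
   (P(k) ∝ k^(−α) e^(−k/κ)) models, selected by R².
4. **Null models** — 1000 uniform G(n, m) random networks with the
   empirical node/edge counts (degree-preserving rewiring available);
   observed indices are compared by Z-tests, and two groups are compared by
   a bootstrap-over-samples z-test per index.
5. **O/R ratios** — for each phylum pair and edge sign, the observed
   incidence O (% of same-sign edges joining the two phyla) over the mean
   incidence R in the random ensemble; O/R > 1 means more co-occurrence
   than chance, with empirical add-one p-values.
6. **Node roles** — within-module connectivity Zi and participation
   Pi = 1 − Σ_s (k_is/k_i)² classify nodes at (Zi, Pi) thresholds
   (2.5, 0.62) into peripherals, connectors, module hubs and network hubs.
7. **Environment** — OTU–environment edges (|ρ| ≥ 0.6, p < 0.05) and
   module eigengenes (first principal component of the standardized member
   profiles) correlated with environmental variables (TN, TP, NH₄, NO₂,
   DOC, pH).

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import micronet as mn

cfg = mn.SyntheticConfig(loading_strength={"weak": 0.5, "strong": 0.95}, seed=1)
ds = mn.generate_two_zone_dataset(cfg)

model = mn.CooccurrenceNetworkModel.from_synthetic(ds)
res = model.fit(group="strong")
print(res.summary())
```

```
Co-occurrence network — group strong
====================================
Samples: 10   OTUs screened: 120
Edge thresholds: |rho| >= 0.9, p < 0.01, q < 0.05
Nodes: 68   Edges: 151 (127 positive, 24 negative)
Modules: 9   Modularity (MD): 0.717
Clustering coefficient (CC): 0.605   Average path length (APL): 1.982
Diameter (ND): 5   Average degree (AD): 4.44   Graph density (GD): 0.066
Node roles (Zi/Pi at 2.5/0.62): peripheral: 68
```

Of the 120 simulated OTUs, 68 carry at least one strong, significant
correlation in the strong-structure zone; the planted 4-module design shows
up as high modularity (0.717) and a mix of positive (127) and negative (24)
edges. Comparing against 200 G(n, m) random networks:

```python
print(res.z_tests(res.null_summary(n=200, seed=1)).round(4))
```

```
       observed  null_mean  null_sd        z       p  degenerate
index
CC       0.6051     0.0667   0.0212  25.3887  0.0000       False
APL      1.9821     2.9271   0.0417 -22.6752  0.0000       False
ND       5.0000     5.9600   0.5384  -1.7831  0.0746       False
MD       0.7170     0.4037   0.0164  19.1180  0.0000       False
```

Clustering and modularity far exceed the random expectation — the network
is non-random. The same results object exposes `res.or_ratios(...)`,
`res.roles`, `res.degree_fit()` and `res.eigengene_env()`; zone contrasts
go through `mn.compare_zones(...)`.

A command line mirrors the library
(`micronet simulate | preprocess | network | indices | null | orratio |
roles | envcorr | run`); `micronet run` writes edge TSVs, Cytoscape-loadable
GraphML, an indices JSON, null-model Z-test reports, O/R tables, node-role
TSVs, eigengene–environment TSVs and a run manifest per zone.

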