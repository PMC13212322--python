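# elementnet

Cross-element gene co-occurrence network analysis for depth-resolved
sediment metagenomes.

## The problem

Estuarine sediments couple microbial iron (Fe) metabolism to carbon,
nitrogen, sulfur and phosphorus cycling. A standard way to probe these
couplings from metagenomes is to quantify gene abundances down a sediment
core and ask which Fe-metabolism genes co-vary with which C/N/S/P-cycling
genes across depth. `elementnet` implements that analysis end to end for
the two-site, depth-stratified study design (an oxic, depth-homogeneous
core with n = 6 sections vs a hypoxic, stratified core with n = 7), along
with a synthetic-data generator that emulates the design with exported
ground truth, so every step of the pipeline is testable against planted
signals.

## The method

1. **Normalization.** Mapped-read counts are length-normalized to RPM
   (reads per million): per sample, `RPM_g = 10^6 (c_g/L_g) / Σ_g (c_g/L_g)`.
2. **Bipartite networks.** For each site and each target cycle X ∈
   {C, N, S, P}, Spearman's ρ is computed for every (Fe gene, X gene)
   pair; an edge requires **|ρ| > 0.7** and Benjamini–Hochberg adjusted
   **q < 0.01** (BH applied per network). At n ≤ 9 samples the two-sided
   p-value is computed *exactly* by enumerating all n! rank pairings — the
   t-approximation is anti-conservative at these sample sizes.
3. **Topology.** Node/edge counts, average (weighted) degree, density,
   diameter, average path length; Louvain modules on the |ρ|-weighted
   graph with the best modularity Q over seeded restarts; hub
   classification — *major hubs* have degree and betweenness both above
   the network's 90th percentile, *connectors* have top-decile betweenness
   but sub-decile degree; module depth profiles as mean per-gene z-scores
   of log1p abundance; per-depth taxon shares of hub Fe genes.
4. **Robustness.** Nodes are removed at random (averaged over replicates)
   or highest-current-degree-first; the fraction of original nodes in the
   largest connected component defines a curve whose trapezoidal AUC
   summarizes tolerance to node loss.
5. **Sensitivity.** Depth-controlled *residual networks* (per-gene OLS of
   log1p RPM on depth, Spearman on residuals) remove correlations induced
   by shared depth gradients; PERMDISP (999 permutations) on Bray–Curtis
   dissimilarities of Hellinger-transformed gene profiles checks that site
   contrasts are not dispersion artifacts; PERMANOVA tests site separation
   of taxon-aggregated Fe-gene profiles.

## Worked example

Run the numbered analysis scripts in order (or `elementnet run-all`):

```sh
python analysis/01_simulate.py
python analysis/02_build_networks.py
python analysis/03_topology_hubs_modules.py
python analysis/04_robustness.py
python analysis/05_residual_networks.py
python analysis/06_community_stats.py
```

With the default seed (1) the run prints, among other things:

```
YZE Fe-C: 1600 pairs tested -> 71 nodes, 449 edges
...
YZE_Fe-C: Q=0.315, 4 modules, 6 major hubs, 0 connectors
...
 OUE     C        605               0
 YZE     C        449              68
...
6% of raw edges survive depth control: the remainder are depth-gradient artifacts
PERMANOVA (Fe-gene taxon profiles, site): R^2=0.217, p=0.0907
PERMDISP Fe-C: F=0.419, p=0.521 (no dispersion difference)
```

Reading: of the 1600 Fe×C pairs tested at the stratified site, 449 pass
the edge thresholds; the network splits into 4 modules (Q = 0.315) with 6
major-hub genes. Only ~6% of raw edges survive depth control — in this
synthetic world most raw co-occurrence is carried by shared monotone depth
trends, exactly the artifact the residual networks are designed to expose
(the surviving residual edges are dominated by the planted correlated
blocks, whose members are trend-free by construction). PERMDISP finds no
site difference in within-site dispersion, so network contrasts are not
dispersion artifacts.

All tabular outputs land under `results/`; `elementnet run-all` writes the
same inventory plus a `manifest.json` with checksums that reproduce byte
for byte under a fixed seed.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on the
default synthetic world:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It simulates the dataset, normalizes, builds all eight networks plus the
residual networks, computes topology, robustness and community statistics,
verifies that the run produced its full output inventory, and writes the
result JSON to `--out`.

## CLI

`elementnet simulate | network | topology | robustness | compare | run-all`
— thin wrappers over the library; see `elementnet --help`.
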