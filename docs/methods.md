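# Methods

This note documents the models, numerical choices and limitations behind
`elementnet`. It states no empirical result that the test suite or the
analysis scripts do not themselves compute.

## Abundance model

Gene abundance is RPM (reads per million), a length-normalized relative
abundance identical in form to TPM: per sample,
`RPM_g = 10^6 (c_g/L_g) / Σ_g (c_g/L_g)` with mapped-read count `c_g` and
gene length `L_g` in bp. Columns sum to 10^6 by construction, and the
quantity is invariant to uniform within-sample count scaling. Genes with
zero counts in every sample are dropped (with a warning) before any
correlation, because constant rows have undefined ranks. When an RPM table
is supplied directly it is accepted as-is; RPM is recomputed only when
counts and lengths are given.

Downstream transforms: `log1p` for regressions and z-scores (RPM contains
exact zeros, so plain log is undefined; wherever a log transform is
ambiguous we use log1p and record it), Hellinger (`sqrt` of relative
abundance; unit-norm columns) ahead of Bray–Curtis for community-level
tests. Bray–Curtis is a semimetric; the triangle inequality is neither
assumed nor asserted.

## Edge statistics

Networks are *bipartite by design*: only (Fe gene, target-cycle gene)
pairs are tested, per target cycle, and BH adjustment is applied per
network, not pooled across the four cycles. Both thresholds are strict:
|ρ| > 0.7 and q < 0.01.

Spearman's ρ is the Pearson correlation of mid-ranks (ties averaged).
Two-sided p-values default to **exact enumeration** for n ≤ 9: the p-value
is the proportion of all n! pairings of the observed rank vectors with
|ρ_perm| ≥ |ρ_obs|. With ties, the observed tied mid-ranks are permuted;
the null distribution depends only on the two rank multisets and is
cached. Exact enumeration is refused above n = 12; a t-approximation with
n−2 df is available (`method="t"`) and is used automatically for n > 9.
The t-approximation is anti-conservative at n = 6–7, which is why exact is
the default at the study's sample sizes.

A structural consequence worth knowing: at n = 6 the smallest attainable
exact p is 2/720 ≈ 0.0028, so with m tested pairs the BH condition
q < 0.01 can only be met when at least ≈ 28% of all pairs are perfectly
rank-correlated. Small-n co-occurrence networks under exact p-values are
therefore all-or-nothing: either the community has pervasive monotone
structure or the network is empty. Published edge counts at such sample
sizes are generally only reachable with asymptotic p-values; both methods
are provided and the method used is recorded in the result metadata.

## Residual (depth-controlled) networks

For each gene, log1p(RPM) is regressed on section-midpoint depth by OLS
with intercept (residuals sum to zero per gene); Spearman correlations are
then computed on residuals and thresholded identically. Genes with
residual variance below 1e−12 (abundance exactly linear in depth) are
dropped with a warning. This removes correlation induced by shared
monotone depth gradients while preserving correlation from shared latent
factors that are not depth-aligned.

## Topology conventions

Shortest paths are unweighted (desktop graph tools' default distance
metrics ignore weights): the diameter is taken on the largest connected
component and the average path length over all reachable ordered pairs.
Betweenness is normalized to [0, 1] with endpoints excluded (divisor
(N−1)(N−2)/2); closeness is the within-component
(reachable count)/(sum of distances) form, 0 for isolated nodes.
`avg_degree = 2E/N` and `density = 2E/(N(N−1))` hold exactly — the
pipeline's summary table can never print an internally inconsistent row.

Modules come from Louvain on the |ρ|-weighted graph at resolution 1.0,
best-Q over 10 seeded restarts, ids relabeled by smallest member node for
determinism. Hub thresholds use numpy's linearly interpolated percentile
with strict comparisons, so a degenerate all-equal network classifies no
hubs. Module depth profiles standardize each gene's log1p abundance by its
own mean and sd (z = 0 everywhere for zero-variance genes, logged) and
average member z per sample. Hub-gene taxonomy shares include both major
hubs and connectors.

## Robustness

LCC fractions are normalized by the *original* node count, so curves end
at (1, 0), and degrees are *recomputed* after each targeted removal
(adaptive attack); ties break by node id for determinism. The AUC is the
trapezoidal integral over removal fraction ∈ [0, 1] including both
endpoints. Random removal averages 100 uniformly shuffled orders by
default. Curves are computed by processing removal orders in reverse as
union-find additions, so whole curves cost ~O((N+E) α) per replicate.
Published AUC values are not comparable across normalization conventions
(original-N vs remaining-N, endpoint handling), so no external AUC value
is treated as a reference here.

## Permutation tests

PERMANOVA uses the standard sum-of-squares partition of squared
dissimilarities, pseudo-F = (SS_b/(g−1))/(SS_w/(n−g)), R² = SS_b/SS_t,
with unrestricted label permutations (the one-factor default of the
standard R implementation) and p = (#{F_perm ≥ F_obs}+1)/(n_perm+1),
floored at 1/(n_perm+1); the default is 9999 permutations. PERMDISP embeds
the matrix by principal coordinates (Gower centering; axes with negative
eigenvalues contribute negatively to squared distances — the standard
imaginary-part correction), measures distances to group *centroids*
(means in PCoA space; the median variant is not implemented), and permutes
group labels over those distances (999 by default). With Euclidean
distances on 1-D data and two groups, the pseudo-F reduces to the
classical one-way ANOVA F (verified in the tests).

## Synthetic world

The generator emulates the target study design: two cores sectioned at
4-cm intervals (midpoints 2…22 and 2…26 cmbsf; n = 6 and n = 7), one
depth-homogeneous and one stratified, with a logistic surface/deep
baseline switch at 8 cmbsf (transition width 2 cm — a hard step would
create exactly tied abundances and degenerate ranks). Surface/deep
preference follows taxonomy (Chloroflexota-, Bathyarchaeota- and
Actinomycetota-affiliated genes prefer the deep layer), which gives the
stratified site a taxonomic contrast with the homogeneous one.

Per-gene latent log-abundance = baseline + slope×depth + stratification
shift + block-factor loading + Gaussian noise. Planted correlated blocks
use a shared Gaussian factor per block (Gaussian copula: target Spearman
ρ_s maps to latent Pearson r = 2 sin(π ρ_s/6); loadings are
λ = σ_noise √(r/(1−r))). Block members are trend-free so their correlation
is governed by the factor alone. Counts are Poisson around the expected
read mass exp(latent)×length, scaled to the configured read depth
(default 2×10^6 mapped reads/sample).

**Noiseless contract.** With `noise_sd = 0` counts are the rounded
expected masses, not Poisson draws — Poisson sampling noise is considered
part of the noise that the switch turns off. This is what makes the
noiseless-recovery guarantee (every planted block pair passes the edge
thresholds) exact. The guarantee applies to *positively loaded* blocks:
RPM closure divides every gene by the same per-sample total, which
preserves perfect concordance but perturbs perfect anti-correlation when
the total itself trends, so mixed-sign blocks recover approximately, not
exactly.

**Calibration of the defaults.** The stated world must produce non-empty
networks at n = 6 under exact p-values, which (see above) requires ≳28%
of tested pairs to be perfectly rank-correlated. The defaults therefore
plant strong monotone depth trends — 95% of genes trending, |slope|
uniform in [0.15, 0.25] log-units/cm (≈36–400× swing over a 24-cm core),
multiplicative noise sd 0.06, baseline sd 0.6. These were fixed once,
against that structural requirement, and are deliberately cleaner than
field data; a green end-to-end test establishes that the machinery is
correct on a world matching the design's assumptions, not that real
sediment profiles are this strongly structured. The null configuration
(`null_config`: no trends, no blocks, no stratification) is used for FDR
calibration and is untouched by this choice.

What the generator does **not** emulate: read-level artifacts (FASTQ,
assembly, misannotation), overdispersed (negative-binomial) counts,
compositional correlations among thousands of genes, or taxon-specific
abundance distributions of real Fe genes; abundance distributions were
chosen for testability, not realism.

## Seeds and determinism

Every stochastic component takes an explicit seed. `run_all` derives
per-stage seeds from the global seed by a fixed affine rule
(`(seed·1000003 + 7919·stage) mod 2^31−1`), writes all tables with a fixed
float format, and emits a manifest (config echo, version, per-file sha256,
warnings) with no timestamps, so identical (config, seed) reproduce the
manifest byte for byte.

## Known limitations

* Exact p-values make small-n networks all-or-nothing (see above); the
  asymptotic alternative is anti-conservative. There is no middle ground
  at n = 6–7, and the package exposes both honestly.
* PERMDISP implements the centroid variant only.
* The hub/connector rule uses within-network percentiles; it is not the
  within/among-module connectivity (Zi–Pi) classification.
* Eigenvector/PageRank centralities, partial-correlation network
  inference (SparCC/SPIEC-EASI), rarefaction and CLR-based compositional
  analysis are out of scope.
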