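"""Synthetic two-estuary, depth-stratified gene-abundance generator.

The generator emulates the statistical structure the network analysis
assumes, with exported ground truth for every planted signal:

* two sediment cores sampled at 4-cm section midpoints (n = 6 and n = 7 by
  default), one depth-homogeneous and one with a surface/deep community
  break at 8 cmbsf (logistic transition, so ranks never tie exactly);
* per-gene monotone depth trends (log-linear slopes);
* planted blocks of cross-cycle correlated genes via a shared Gaussian
  latent factor (Gaussian copula: a target Spearman rho_s maps to a latent
  Pearson r = 2 sin(pi * rho_s / 6));
* integer mapped-read counts drawn from a Poisson around the expected read
  mass exp(latent) * gene_length, scaled to the configured read depth.

With ``noise_sd == 0`` the generator is fully deterministic given the
latent construction: counts are the rounded expected read masses rather
than Poisson draws, so noiseless planted blocks survive rank correlation
exactly.  Poisson sampling noise is treated as part of the "noise" the
``noise_sd`` switch controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from elementnet.config import CYCLES, SyntheticConfig

logger = logging.getLogger(__name__)

#: Functional category vocabulary per elemental cycle.  Fe categories follow
#: the standard iron-metabolism gene groupings (redox, acquisition,
#: homeostasis); other cycles use pathway-level groupings.
CATEGORY_VOCAB: dict[str, tuple[str, ...]] = {
    "Fe": (
        "iron_oxidation",
        "dissimilatory_iron_reduction",
        "siderophore_synthesis",
        "siderophore_transport",
        "iron_transport",
        "heme_utilization",
        "heme_transport",
        "iron_regulation",
        "iron_storage",
    ),
    "C": (
        "carbon_fixation",
        "respiratory_carbon_release",
        "organic_biosynthesis",
        "organic_degradation",
        "organic_transformation",
        "substrate_transport",
    ),
    "N": (
        "nitrification",
        "denitrification",
        "DNRA",
        "anammox",
        "nitrogen_fixation",
        "urea_degradation",
    ),
    "S": (
        "dissimilatory_sulfate_reduction",
        "assimilatory_sulfate_reduction",
        "inorganic_sulfur_oxidation",
        "organic_sulfur_transformation",
    ),
    "P": (
        "phosphonate_degradation",
        "polyphosphate_metabolism",
        "phosphate_transport",
        "organic_P_mineralization",
    ),
}

TAXA = (
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Deltaproteobacteria",
    "Thermodesulfobacteriota",
    "Chloroflexota",
    "Ca_Bathyarchaeota",
    "Actinomycetota",
    "Acidobacteriota",
    "Nitrospirota",
)

#: Taxa enriched below the stratification depth at stratified sites; the
#: remaining taxa prefer the surface layer.  This couples the community
#: break to taxonomy, so stratified and homogeneous sites differ in their
#: taxon-aggregated profiles (as hypoxic vs oxic estuary cores do).
DEEP_TAXA = frozenset({"Chloroflexota", "Ca_Bathyarchaeota", "Actinomycetota"})


@dataclass
class GroundTruth:
    """Exported truth for every planted signal.

    ``planted_edges``: one row per in-block cross-cycle (Fe, target) pair
    with the loading-product sign and the target |rho|.
    ``trend_genes``: realized depth slope per gene (log-units per cm).
    ``block_membership``: gene -> block name for block members.
    """

    planted_edges: pd.DataFrame
    trend_genes: pd.DataFrame
    block_membership: pd.Series


def generate_catalog(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the gene annotation catalog.

    Returns a DataFrame indexed by gene_id with columns ``cycle``,
    ``category``, ``taxon`` and ``length_bp``.  Deterministic in
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = []
    lo, hi = config.length_range
    for cycle in CYCLES:
        n = config.n_genes_per_cycle.get(cycle, 0)
        vocab = CATEGORY_VOCAB[cycle]
        for i in range(n):
            records.append(
                {
                    "gene_id": f"{cycle}_{i:04d}",
                    "cycle": cycle,
                    "category": vocab[int(rng.integers(len(vocab)))],
                    "taxon": TAXA[int(rng.integers(len(TAXA)))],
                    "length_bp": int(rng.integers(lo, hi + 1)),
                }
            )
    return pd.DataFrame.from_records(records).set_index("gene_id")


def _sample_frame(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for site in config.sites:
        for depth in site.depths:
            rows.append(
                {"sample_id": f"{site.name}_{int(round(depth)):02d}cm", "site": site.name, "depth_cmbsf": float(depth)}
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids; depths within a site must be distinct")
    return meta


def _assign_blocks(catalog: pd.DataFrame, config: SyntheticConfig) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Assign block members, loadings signs and targets.

    Members are taken in catalog order per cycle, consumed sequentially
    across blocks (deterministic).  Returns (block_name, loading_sign,
    target_rho) per member gene.
    """
    cursor = {c: 0 for c in CYCLES}
    names, signs, targets = {}, {}, {}
    by_cycle = {c: list(catalog.index[catalog["cycle"] == c]) for c in CYCLES}
    for bi, block in enumerate(config.blocks):
        bname = block.name or f"block_{bi}"
        for cyc, cnt in block.members.items():
            avail = by_cycle[cyc]
            if cursor[cyc] + cnt > len(avail):
                raise ValueError(f"block {bname!r} requests more {cyc} genes than the catalog holds")
            chosen = avail[cursor[cyc] : cursor[cyc] + cnt]
            cursor[cyc] += cnt
            n_neg = block.negative.get(cyc, 0)
            for j, g in enumerate(chosen):
                names[g] = bname
                signs[g] = -1.0 if j < n_neg else 1.0
                targets[g] = block.target_rho
    return (pd.Series(names, dtype=object), pd.Series(signs, dtype=float), pd.Series(targets, dtype=float))


def _latent_loading(target_rho: float, noise_sd: float) -> float:
    """Factor loading giving latent Pearson r = 2 sin(pi*rho/6) between two
    block members with independent N(0, noise_sd) residuals."""
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    if noise_sd == 0.0:
        return 1.0  # pure factor: achieved rho is 1 regardless of target
    r = min(r, 0.9999)  # target 1 is unreachable with noise; approximate
    return noise_sd * np.sqrt(r / (1.0 - r))


def generate_counts(catalog: pd.DataFrame, config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw gene x sample integer mapped-read counts plus ground truth.

    Latent log-abundance per gene and sample:
    ``baseline + slope*depth + strat_shift(depth) + loading*factor + noise``.
    Counts have mean proportional to ``exp(latent) * length`` scaled so each
    sample's expected total equals ``read_depth``.
    """
    config.validate()
    if catalog.empty:
        raise ValueError("empty gene catalog")
    for site in config.sites:
        if len(site.depths) < 3:
            raise ValueError(f"site {site.name!r} has fewer than 3 samples; correlation undefined downstream")

    rng = np.random.default_rng(config.seed + 1)  # independent of catalog stream
    genes = list(catalog.index)
    meta = _sample_frame(config)
    n_genes, n_samples = len(genes), len(meta)
    depths = meta["depth_cmbsf"].to_numpy()
    site_of = meta["site"].to_numpy()
    stratified = {s.name: s.stratified for s in config.sites}

    block_name, block_sign, block_target = _assign_blocks(catalog, config)
    in_block = catalog.index.isin(block_name.index)

    baseline = rng.normal(0.0, config.baseline_sd, size=n_genes)
    # Depth slopes: a trend_fraction of genes get a strong log-linear slope
    # of random sign; block members stay trend-free so their correlation is
    # governed by the planted factor alone.
    slo, shi = config.slope_range
    has_trend = rng.random(n_genes) < config.trend_fraction
    slopes = np.where(
        has_trend,
        rng.choice([-1.0, 1.0], size=n_genes) * rng.uniform(slo, shi, size=n_genes),
        0.0,
    )
    slopes[in_block] = 0.0
    # Surface/deep preference follows taxonomy; exercised only at
    # stratified sites.
    strat_pref = np.where(catalog["taxon"].isin(DEEP_TAXA).to_numpy(), 1.0, -1.0)
    strat_pref[in_block] = 0.0

    latent = baseline[:, None] + slopes[:, None] * depths[None, :]
    if config.stratification_amplitude != 0.0:
        scale = max(config.stratification_width / 2.0, 1e-9)
        switch = expit((depths - config.stratification_depth) / scale) - 0.5
        strat_mask = np.array([stratified[s] for s in site_of], dtype=float)
        latent += config.stratification_amplitude * strat_pref[:, None] * (switch * strat_mask)[None, :]

    # Planted correlated blocks: one latent factor per block per sample.
    gene_pos = {g: i for i, g in enumerate(genes)}
    for bname in pd.unique(block_name.values) if len(block_name) else []:
        members = block_name.index[block_name.values == bname]
        factor = rng.normal(0.0, 1.0, size=n_samples)
        for g in members:
            lam = _latent_loading(float(block_target[g]), config.noise_sd)
            if config.noise_sd > 0 and float(block_target[g]) >= 1.0:
                logger.warning("block %s target |rho|=1 with noise_sd>0 is approximated (r clipped)", bname)
            latent[gene_pos[g], :] += block_sign[g] * lam * factor

    if config.noise_sd > 0:
        latent += rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    lengths = catalog["length_bp"].to_numpy(float)
    mass = np.exp(latent) * lengths[:, None]
    mu = config.read_depth * mass / mass.sum(axis=0, keepdims=True)
    if config.noise_sd > 0:
        counts = rng.poisson(mu)
    else:
        counts = np.rint(mu).astype(np.int64)  # noiseless contract: deterministic
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=meta.index)

    truth = _ground_truth(catalog, block_name, block_sign, block_target, genes, slopes)
    return counts_df, truth


def _ground_truth(catalog, block_name, block_sign, block_target, genes, slopes) -> GroundTruth:
    edges = []
    for bname in pd.unique(block_name.values) if len(block_name) else []:
        members = list(block_name.index[block_name.values == bname])
        fe = [g for g in members if catalog.loc[g, "cycle"] == "Fe"]
        other = [g for g in members if catalog.loc[g, "cycle"] != "Fe"]
        for a in fe:
            for b in other:
                edges.append(
                    {
                        "fe_gene": a,
                        "target_gene": b,
                        "target_cycle": catalog.loc[b, "cycle"],
                        "sign": int(block_sign[a] * block_sign[b]),
                        "target_rho": float(block_target[a]),
                        "block": bname,
                    }
                )
    planted = pd.DataFrame(edges, columns=["fe_gene", "target_gene", "target_cycle", "sign", "target_rho", "block"])
    trends = pd.DataFrame({"gene_id": genes, "slope": slopes}).set_index("gene_id")
    return GroundTruth(planted_edges=planted, trend_genes=trends, block_membership=block_name)


def generate_dataset(config: SyntheticConfig):
    """Convenience wrapper: (counts, catalog, sample_meta, ground_truth)."""
    catalog = generate_catalog(config)
    counts, truth = generate_counts(catalog, config)
    return counts, catalog, _sample_frame(config), truth
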