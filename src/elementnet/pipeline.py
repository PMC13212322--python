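"""End-to-end orchestration: simulate/ingest -> normalize -> networks ->
topology -> robustness -> residual networks -> community statistics.

`run_all` executes every stage for each site, writes all tabular outputs
under the configured output directory and finishes with a ``manifest.json``
recording the config echo, package version, per-stage seeds, a sha256
checksum for every output file and all warnings raised along the way.  The
manifest contains no timestamps: re-running with the same config and seed
reproduces it byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

import elementnet
from elementnet.abundance import AbundanceTable, aggregate_by_group, bray_curtis, compute_rpm, hellinger_transform
from elementnet.config import TARGET_CYCLES, RunConfig, stage_seed
from elementnet import io as enio
from elementnet.netbuild import build_network, correlate_bipartite, residual_network
from elementnet.robustness import removal_curve
from elementnet.stats import permanova, permdisp
from elementnet.synth import generate_dataset
from elementnet.topology import (
    classify_hubs,
    detect_modules,
    hub_taxonomy_summary,
    module_depth_profile,
    node_metrics,
    summarize_topology,
)

logger = logging.getLogger(__name__)

STAGES = ("data", "networks", "topology", "robustness", "residual", "stats")


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def _load_or_simulate(config: RunConfig):
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    counts = enio.read_counts(config.counts_path)
    annotation = enio.read_annotation(config.annotation_path)
    samples = enio.read_samples(config.samples_path)
    return counts, annotation, samples, None


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("elementnet").addHandler(collector)
    files: list[Path] = []
    stage_seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(STAGES)}
    current_stage = "setup"
    try:
        # --- data ---------------------------------------------------------
        current_stage = "data"
        counts, annotation, samples, truth = _load_or_simulate(config)
        files.append(enio.write_counts(counts, out / "data" / "counts.tsv"))
        files.append(enio.write_annotation(annotation, out / "data" / "annotation.tsv"))
        files.append(enio.write_samples(samples, out / "data" / "samples.tsv"))
        if truth is not None:
            files.extend(enio.write_ground_truth(truth, out / "data"))
        lengths = annotation["length_bp"]
        rpm = compute_rpm(counts, lengths, samples)
        files.append(enio.write_abundance(rpm, out / "data" / "rpm.tsv"))

        sites = sorted(samples["site"].unique())
        site_tables = {
            s: rpm.subset_samples(list(samples.index[samples["site"] == s])) for s in sites
        }

        # --- networks -----------------------------------------------------
        current_stage = "networks"
        cycles_present = [c for c in TARGET_CYCLES if (annotation["cycle"] == c).any()]
        for c in TARGET_CYCLES:
            if c not in cycles_present:
                logger.warning("no %s-cycle genes in the catalog; skipping Fe-%s networks", c, c)
        networks: dict[tuple[str, str], object] = {}
        for site in sites:
            for cycle in cycles_present:
                cors = correlate_bipartite(site_tables[site], annotation, cycle, method=config.p_method)
                net = build_network(cors, annotation, cycle, rho_min=config.rho_min, q_max=config.q_max)
                networks[(site, cycle)] = net
                files.append(enio.write_edges(net, out / "networks" / f"{site}_Fe-{cycle}_edges.tsv"))
                if net.n_nodes:
                    files.append(enio.write_graphml(net, out / "networks" / f"{site}_Fe-{cycle}.graphml"))

        # --- topology -----------------------------------------------------
        current_stage = "topology"
        topo_rows = {}
        seed_topo = stage_seeds["topology"]
        for (site, cycle), net in networks.items():
            label = f"{site} Fe-{cycle}"
            if net.n_nodes < 2:
                logger.warning("skipping topology for empty/degenerate network %s", label)
                continue
            partition, q = detect_modules(
                net, resolution=config.module_resolution, seed=seed_topo, restarts=config.module_restarts
            )
            summary = summarize_topology(net, partition=partition)
            topo_rows[label] = summary.to_series()
            metrics = node_metrics(net)
            hubs = classify_hubs(metrics, pct=config.hub_percentile)
            files.append(enio.write_tsv(hubs, out / "topology" / f"hubs_{site}_Fe-{cycle}.tsv", index_label="gene_id"))
            part_df = pd.Series(partition, name="module").rename_axis("gene_id").sort_index().to_frame()
            files.append(enio.write_tsv(part_df, out / "topology" / f"modules_{site}_Fe-{cycle}.tsv"))
            member_table = site_tables[site].subset_genes([g for g in partition if g in site_tables[site].values.index])
            profile = module_depth_profile(member_table, partition)
            files.append(
                enio.write_tsv(profile, out / "topology" / f"module_profiles_{site}_Fe-{cycle}.tsv", index_label="module")
            )
            taxsum = hub_taxonomy_summary(hubs, annotation, site_tables[site])
            if not taxsum.empty:
                files.append(
                    enio.write_tsv(taxsum, out / "topology" / f"hub_taxonomy_{site}_Fe-{cycle}.tsv", index_label="taxon")
                )
        if topo_rows:
            topo_table = pd.DataFrame(topo_rows)
            files.append(enio.write_tsv(topo_table, out / "topology" / "topology_summary.tsv", index_label="Network property"))

        # --- robustness ---------------------------------------------------
        current_stage = "robustness"
        seed_rob = stage_seeds["robustness"]
        curve_frames, auc_rows = [], []
        for i, ((site, cycle), net) in enumerate(sorted(networks.items())):
            if net.n_nodes < 2:
                continue
            for strat in config.robustness_strategies:
                res = removal_curve(net, strat, seed=seed_rob + i, replicates=config.robustness_replicates)
                frame = res.to_frame()
                frame.insert(0, "network", f"{site}_Fe-{cycle}")
                curve_frames.append(frame)
                auc_rows.append(
                    {"network": f"{site}_Fe-{cycle}", "strategy": strat, "auc": res.auc, "replicates": res.replicates}
                )
        if curve_frames:
            curves_path = out / "robustness" / "curves.tsv"
            curves_path.parent.mkdir(parents=True, exist_ok=True)
            pd.concat(curve_frames, ignore_index=True).to_csv(curves_path, sep="\t", index=False, float_format="%.10g")
            files.append(curves_path)
            auc_path = out / "robustness" / "auc.tsv"
            pd.DataFrame(auc_rows).to_csv(auc_path, sep="\t", index=False, float_format="%.10g")
            files.append(auc_path)

        # --- residual networks -------------------------------------------
        current_stage = "residual"
        resid_rows = []
        for site in sites:
            for cycle in cycles_present:
                rnet = residual_network(
                    site_tables[site], annotation, cycle, rho_min=config.rho_min, q_max=config.q_max,
                    method=config.p_method,
                )
                files.append(enio.write_edges(rnet, out / "residual" / f"{site}_Fe-{cycle}_edges.tsv"))
                resid_rows.append(
                    {
                        "site": site,
                        "cycle": cycle,
                        "raw_edges": networks[(site, cycle)].n_edges,
                        "residual_edges": rnet.n_edges,
                    }
                )
        files.append(enio.write_tsv(pd.DataFrame(resid_rows), out / "residual" / "edge_counts.tsv"))

        # --- comparative statistics --------------------------------------
        current_stage = "stats"
        stats_out: dict[str, dict] = {}
        if len(sites) >= 2 and samples.groupby("site").size().min() >= 2:
            # PERMANOVA on taxon-aggregated Fe-gene profiles across sites.
            fe_genes = [g for g in annotation.index[annotation["cycle"] == "Fe"] if g in rpm.values.index]
            fe_table = rpm.subset_genes(fe_genes)
            taxa = aggregate_by_group(fe_table, annotation["taxon"], relative=True)
            d = bray_curtis(hellinger_transform(taxa))
            res = permanova(d, samples["site"], n_perm=config.n_perm_permanova, seed=stage_seeds["stats"])
            stats_out["permanova_fe_taxa"] = res.to_dict()
            # PERMDISP per cycle-pair gene set.
            for cycle in cycles_present:
                genes = [
                    g
                    for g in annotation.index[annotation["cycle"].isin(["Fe", cycle])]
                    if g in rpm.values.index
                ]
                d_c = bray_curtis(hellinger_transform(rpm.subset_genes(genes)))
                res_c = permdisp(d_c, samples["site"], n_perm=config.n_perm_permdisp, seed=stage_seeds["stats"] + 1)
                stats_out[f"permdisp_Fe-{cycle}"] = res_c.to_dict()
        else:
            logger.warning("fewer than two sites with >=2 samples; skipping PERMANOVA/PERMDISP")
        stats_path = out / "stats" / "comparative_stats.json"
        stats_path.parent.mkdir(parents=True, exist_ok=True)
        stats_path.write_text(json.dumps(stats_out, indent=2, sort_keys=True) + "\n")
        files.append(stats_path)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current_stage}\nerror={exc}\n")
        logging.getLogger("elementnet").removeHandler(collector)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    logging.getLogger("elementnet").removeHandler(collector)

    manifest = {
        "package": "elementnet",
        "version": elementnet.__version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "files": {str(p.relative_to(out)): enio.sha256_of(p) for p in sorted(files)},
        "warnings": collector.messages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
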