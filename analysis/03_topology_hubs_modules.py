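"""Characterize each network: summary table, hub genes, modules, profiles.

Produces the structural-property table (nodes, links, average degree,
weighted degree, diameter, density, modularity, average path length), the
hub/connector classification at the 90th percentile, Louvain module
assignments, module depth z-score profiles and per-depth taxon shares of
hub Fe genes.  Outputs under results/topology/.
"""

from pathlib import Path

import pandas as pd

import elementnet as en
from elementnet import io as enio
from elementnet.topology import classify_hubs, detect_modules, hub_taxonomy_summary, module_depth_profile, node_metrics

DATA = Path("results/data")
NETS = Path("results/networks")
OUT = Path("results/topology")
SEED = 1


def main() -> None:
    counts = enio.read_counts(DATA / "counts.tsv")
    catalog = enio.read_annotation(DATA / "annotation.tsv")
    samples = enio.read_samples(DATA / "samples.tsv")
    rpm = en.compute_rpm(counts, catalog["length_bp"], samples)
    rows = {}
    for path in sorted(NETS.glob("*.graphml")):
        name = path.stem  # e.g. YZE_Fe-C
        site = name.split("_")[0]
        g = enio.read_graphml(path)
        partition, q = detect_modules(g, seed=SEED)
        summary = en.summarize_topology(g, partition=partition)
        rows[name] = summary.to_series()
        metrics = node_metrics(g)
        hubs = classify_hubs(metrics)
        enio.write_tsv(hubs, OUT / f"hubs_{name}.tsv", index_label="gene_id")
        site_table = rpm.subset_samples(list(samples.index[samples["site"] == site]))
        members = site_table.subset_genes([gn for gn in partition if gn in site_table.values.index])
        enio.write_tsv(module_depth_profile(members, partition), OUT / f"module_profiles_{name}.tsv", index_label="module")
        tax = hub_taxonomy_summary(hubs, catalog, site_table)
        if not tax.empty:
            enio.write_tsv(tax, OUT / f"hub_taxonomy_{name}.tsv", index_label="taxon")
        n_hub = int((hubs["role"] == "major_hub").sum())
        n_con = int((hubs["role"] == "connector").sum())
        print(f"{name}: Q={q:.3f}, {len(set(partition.values()))} modules, {n_hub} major hubs, {n_con} connectors")
    table = pd.DataFrame(rows)
    enio.write_tsv(table, OUT / "topology_summary.tsv", index_label="Network property")
    print("\nStructural properties:")
    print(table.round(2).to_string())


if __name__ == "__main__":
    main()
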