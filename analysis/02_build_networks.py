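"""Normalize to RPM and build the eight bipartite Fe-X co-occurrence networks.

For each site and each target cycle (C, N, S, P), Spearman correlations are
computed between every Fe gene and every target-cycle gene; edges require
|rho| > 0.7 and BH FDR q < 0.01 (exact permutation p-values at these sample
sizes).  Edge lists and GraphML files go to results/networks/.
"""

from pathlib import Path

import elementnet as en
from elementnet import io as enio

DATA = Path("results/data")
OUT = Path("results/networks")


def main() -> None:
    counts = enio.read_counts(DATA / "counts.tsv")
    catalog = enio.read_annotation(DATA / "annotation.tsv")
    samples = enio.read_samples(DATA / "samples.tsv")
    rpm = en.compute_rpm(counts, catalog["length_bp"], samples)
    enio.write_abundance(rpm, DATA / "rpm.tsv")
    for site in sorted(samples["site"].unique()):
        table = rpm.subset_samples(list(samples.index[samples["site"] == site]))
        for cycle in "CNSP":
            cors = en.correlate_bipartite(table, catalog, cycle)
            net = en.build_network(cors, catalog, cycle)
            enio.write_edges(net, OUT / f"{site}_Fe-{cycle}_edges.tsv")
            if net.n_nodes:
                enio.write_graphml(net, OUT / f"{site}_Fe-{cycle}.graphml")
            print(f"{site} Fe-{cycle}: {len(cors)} pairs tested -> {net.n_nodes} nodes, {net.n_edges} edges")


if __name__ == "__main__":
    main()
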