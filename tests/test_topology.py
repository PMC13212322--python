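"""Topology, hub classification, module detection and depth profiles,
checked against brute-force shortest-path / modularity oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from elementnet.topology import (
    classify_hubs,
    detect_modules,
    hub_taxonomy_summary,
    modularity_of,
    module_depth_profile,
    node_metrics,
    summarize_topology,
)
from tests.conftest import make_annotation, make_table

# ---------------------------------------------------------------------------
# brute-force graph oracles (BFS-free: explicit path enumeration, N <= 8)


def _all_simple_paths(g, s, t):
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(list(path))
            return
        for nb in g.neighbors(node):
            if nb not in seen:
                walk(nb, seen | {nb}, path + [nb])

    walk(s, {s}, [s])
    return paths


def _oracle_metrics(g):
    """(distances, betweenness, closeness) by shortest-path enumeration."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    dist = {}
    sp = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(g, s, t)
        if not paths:
            continue
        dmin = min(len(p) - 1 for p in paths)
        dist[(s, t)] = dmin
        sp[(s, t)] = [p for p in paths if len(p) - 1 == dmin]
    btw = {v: 0.0 for v in nodes}
    for (s, t), shortest in sp.items():
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in shortest) / len(shortest)
            btw[v] += frac
    scale = (n - 1) * (n - 2) / 2.0
    btw = {v: b / scale for v, b in btw.items()}
    clo = {}
    for v in nodes:
        ds = [d for (s, t), d in dist.items() if v in (s, t)]
        clo[v] = (len(ds) / sum(ds)) if ds else 0.0
    return dist, btw, clo


def _oracle_modularity(g, partition):
    m = sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    deg = {v: 0.0 for v in g.nodes}
    for a, b, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        deg[a] += w
        deg[b] += w
    q = 0.0
    for a, b, d in g.edges(data=True):
        if partition[a] == partition[b]:
            q += d.get("weight", 1.0) / m
    for comm in set(partition.values()):
        s = sum(deg[v] for v in partition if partition[v] == comm)
        q -= (s / (2 * m)) ** 2
    return q


def _random_graph(rng, n=7, p=0.45):
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() >= 2:
            return g


# ---------------------------------------------------------------------------


class TestSummarizeTopology:
    def test_path_graph_closed_forms(self):
        g = nx.path_graph(4)
        s = summarize_topology(g, partition={v: 0 for v in g})
        assert s.diameter == 3
        assert s.avg_path_length == pytest.approx(5 / 3)
        assert s.avg_degree == pytest.approx(2 * 3 / 4)
        assert s.graph_density == pytest.approx(0.5)

    def test_triangle(self):
        g = nx.complete_graph(3)
        s = summarize_topology(g, partition={v: 0 for v in g})
        assert (s.graph_density, s.diameter, s.avg_path_length) == (1.0, 1, 1.0)

    def test_identities_on_random_graphs(self, rng):
        for _ in range(5):
            g = _random_graph(rng)
            s = summarize_topology(g, seed=1)
            assert s.avg_degree == pytest.approx(2 * s.n_links / s.n_nodes)
            assert s.graph_density == pytest.approx(2 * s.n_links / (s.n_nodes * (s.n_nodes - 1)))
            if nx.is_connected(g):
                assert s.diameter >= s.avg_path_length

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_topology(nx.Graph())


class TestNodeMetrics:
    def test_path_and_star_betweenness(self):
        m = node_metrics(nx.path_graph(3))
        assert m.loc[1, "betweenness"] == pytest.approx(1.0)
        for n in (4, 6, 8):
            star = nx.star_graph(n - 1)  # node 0 is the center
            ms = node_metrics(star)
            assert ms.loc[0, "betweenness"] == pytest.approx(1.0)

    def test_degree_sum_is_2e(self, rng):
        g = _random_graph(rng)
        m = node_metrics(g)
        assert m["degree"].sum() == 2 * g.number_of_edges()

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(4):
            g = _random_graph(rng, n=7)
            m = node_metrics(g)
            _, btw, clo = _oracle_metrics(g)
            for v in g.nodes:
                assert m.loc[v, "betweenness"] == pytest.approx(btw[v], abs=1e-9)
                assert m.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)

    def test_oracle_path_lengths_and_diameter(self, rng):
        for _ in range(4):
            g = _random_graph(rng, n=7)
            dist, _, _ = _oracle_metrics(g)
            s = summarize_topology(g, partition={v: 0 for v in g})
            comp = max(nx.connected_components(g), key=len)
            lcc_d = [d for (a, b), d in dist.items() if a in comp and b in comp]
            assert s.diameter == max(lcc_d)
            assert s.avg_path_length == pytest.approx(np.mean(list(dist.values())))


class TestClassifyHubs:
    def test_degenerate_distribution_has_no_hubs(self):
        hubs = classify_hubs(node_metrics(nx.cycle_graph(10)))
        assert (hubs["role"] == "none").all()

    def test_dominant_node_is_major_hub(self):
        g = nx.star_graph(9)
        g.add_edge(1, 2)
        hubs = classify_hubs(node_metrics(g))
        assert hubs.loc[0, "role"] == "major_hub"

    def test_bridge_node_is_connector(self):
        # two cliques joined through a low-degree bridge
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_node(10)
        g.add_edge(0, 10)
        g.add_edge(10, 5)
        hubs = classify_hubs(node_metrics(g))
        assert hubs.loc[10, "role"] == "connector"

    def test_rules_verified_exhaustively_on_small_graphs(self, rng):
        for _ in range(10):
            g = _random_graph(rng, n=6)
            m = node_metrics(g)
            hubs = classify_hubs(m)
            dthr = np.percentile(m["degree"], 90)
            bthr = np.percentile(m["betweenness"], 90)
            for v in m.index:
                k, b = m.loc[v, "degree"], m.loc[v, "betweenness"]
                expect = "major_hub" if (k > dthr and b > bthr) else ("connector" if (b > bthr and k < dthr) else "none")
                assert hubs.loc[v, "role"] == expect


class TestDetectModules:
    def test_two_triangles_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        partition, q = detect_modules(g, seed=1)
        assert q == pytest.approx(0.5)
        assert len({partition[v] for v in (0, 1, 2)}) == 1
        assert partition[0] != partition[3]

    def test_complete_graph_single_module(self):
        partition, q = detect_modules(nx.complete_graph(6), seed=1)
        assert len(set(partition.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_q_reevaluation_oracle_and_singleton_bound(self, rng):
        for _ in range(5):
            g = _random_graph(rng)
            for a, b in g.edges:
                g.edges[a, b]["weight"] = float(rng.uniform(0.5, 1.0))
            partition, q = detect_modules(g, seed=2)
            assert q == pytest.approx(_oracle_modularity(g, partition))
            singleton = {v: i for i, v in enumerate(g.nodes)}
            assert q >= _oracle_modularity(g, singleton) - 1e-12

    def test_deterministic_given_seed(self, rng):
        g = _random_graph(rng, n=8)
        assert detect_modules(g, seed=7) == detect_modules(g, seed=7)


class TestModuleDepthProfile:
    def test_single_gene_module_is_own_z(self):
        table = make_table([[1.0, 3.0, 9.0, 27.0]])
        prof = module_depth_profile(table, {"g0": 0})
        z = np.log1p(table.values.iloc[0])
        z = (z - z.mean()) / z.std(ddof=0)
        assert np.allclose(prof.loc[0].to_numpy(), z)
        assert prof.loc[0].sum() == pytest.approx(0.0)

    def test_identical_genes_average_to_same_profile(self):
        table = make_table([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
        prof = module_depth_profile(table, {"g0": 0, "g1": 0})
        single = module_depth_profile(table, {"g0": 0})
        assert np.allclose(prof.to_numpy(), single.to_numpy())

    def test_surface_enriched_module_sign_pattern(self):
        depths = [2.0, 6.0, 10.0, 14.0]
        # step-function module: high above 8 cmbsf, low below
        table = make_table([[100.0, 90.0, 1.0, 2.0], [80.0, 110.0, 2.0, 1.0]], depths=depths)
        prof = module_depth_profile(table, {"g0": 0, "g1": 0})
        vals = prof.loc[0].to_numpy()
        assert (vals[:2] > 0).all() and (vals[2:] < 0).all()

    def test_missing_module_rejected(self):
        table = make_table([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            module_depth_profile(table, {"absent_gene": 5})


class TestHubTaxonomy:
    def test_shares_sum_to_one_and_single_taxon_case(self, rng):
        genes = {"fe0": "Fe", "fe1": "Fe", "c0": "C"}
        ann = make_annotation(genes, taxa=["TaxA", "TaxB", "TaxC"])
        table = make_table(rng.uniform(1, 10, size=(3, 4)), gene_ids=list(genes))
        hubs = node_metrics(nx.path_graph(3)).iloc[:0]  # start empty, craft roles below
        import pandas as pd

        hubs = pd.DataFrame({"role": ["major_hub", "connector", "none"]}, index=["fe0", "fe1", "c0"])
        shares = hub_taxonomy_summary(hubs, ann, table)
        assert np.allclose(shares.sum(axis=0), 1.0)
        only = hub_taxonomy_summary(pd.DataFrame({"role": ["major_hub"]}, index=["fe0"]), ann, table)
        assert np.allclose(only.loc["TaxA"].to_numpy(), 1.0)

    def test_no_fe_hubs_yields_empty(self):
        import pandas as pd

        ann = make_annotation({"c0": "C"})
        table = make_table([[1.0, 2.0]], gene_ids=["c0"])
        out = hub_taxonomy_summary(pd.DataFrame({"role": ["major_hub"]}, index=["c0"]), ann, table)
        assert out.empty
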