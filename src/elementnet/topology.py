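"""Network- and node-level topology, hubs, modules and depth profiles.

Conventions (matching the common defaults of desktop graph tools):

* shortest paths are unweighted; diameter is taken on the largest
  connected component, average path length over all reachable ordered
  pairs;
* betweenness is normalized to [0, 1] (endpoints excluded, divisor
  (N-1)(N-2)/2 for undirected graphs); closeness is the within-component
  (reachable count)/(sum of distances) form, 0 for isolated nodes;
* modules come from seeded Louvain restarts on the |rho|-weighted graph,
  keeping the best-modularity partition;
* hub classification uses linearly interpolated percentiles with the
  strict inequalities "degree AND betweenness > 90th percentile" for
  major hubs and "betweenness > 90th, degree < 90th" for connectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from elementnet.abundance import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avg_degree: float
    avg_weighted_degree: float
    diameter: int
    graph_density: float
    modularity: float
    avg_path_length: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Number of nodes": self.n_nodes,
                "Number of links": self.n_links,
                "Average node degree": self.avg_degree,
                "Average weighted degree": self.avg_weighted_degree,
                "Network diameter": self.diameter,
                "Graph density": self.graph_density,
                "Modularity": self.modularity,
                "Average path length": self.avg_path_length,
            }
        )


def _unwrap(net) -> nx.Graph:
    return net.graph if hasattr(net, "graph") and isinstance(net.graph, nx.Graph) else net


def _path_stats(g: nx.Graph) -> tuple[int, float]:
    """(diameter of LCC, mean shortest-path length over reachable ordered pairs)."""
    total, count = 0, 0
    diam = 0
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    for comp in components:
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for target, d in dists.items():
                if d > 0:
                    total += d
                    count += 1
                    if comp == largest and d > diam:
                        diam = d
    apl = total / count if count else float("nan")
    return diam, apl


def summarize_topology(net, partition: dict | None = None, seed: int = 0, resolution: float = 1.0, restarts: int = 10) -> TopologySummary:
    """Table-style structural summary of one co-occurrence network.

    ``avg_degree = 2E/N`` and ``graph_density = 2E/(N(N-1))`` hold exactly;
    weighted degree uses edge weight |rho|.  Modularity is that of the
    supplied partition, or of a fresh Louvain detection.
    """
    g = _unwrap(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if partition is None:
        partition, q = detect_modules(net, resolution=resolution, seed=seed, restarts=restarts)
    else:
        q = modularity_of(net, partition)
    wdeg = sum(d for _, d in g.degree(weight="weight")) / n
    diam, apl = _path_stats(g)
    return TopologySummary(
        n_nodes=n,
        n_links=e,
        avg_degree=2.0 * e / n,
        avg_weighted_degree=wdeg,
        diameter=diam,
        graph_density=2.0 * e / (n * (n - 1)),
        modularity=q,
        avg_path_length=apl,
    )


def node_metrics(net) -> pd.DataFrame:
    """Degree, normalized betweenness, closeness and their percentile ranks.

    Percentile rank is the 'weak' form (percent of nodes with value <= own).
    """
    g = _unwrap(net)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True, weight=None)
    clo = nx.closeness_centrality(g, wf_improved=False)
    nodes = sorted(g.nodes)
    df = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    for col in ("degree", "betweenness"):
        vals = df[col].to_numpy(float)
        df[f"{col}_pctl"] = [100.0 * np.mean(vals <= v) for v in vals]
    return df


def classify_hubs(metrics: pd.DataFrame, pct: float = 90.0) -> pd.DataFrame:
    """Classify nodes as major hubs, connectors, or neither.

    major_hub: degree > P_pct(degree) AND betweenness > P_pct(betweenness);
    connector: betweenness > P_pct(betweenness) AND degree < P_pct(degree).
    Thresholds use numpy's linearly interpolated percentile; comparisons are
    strict, so a degenerate all-equal network yields no hubs.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 nodes")
    deg = metrics["degree"].to_numpy(float)
    btw = metrics["betweenness"].to_numpy(float)
    deg_thr = float(np.percentile(deg, pct))
    btw_thr = float(np.percentile(btw, pct))
    role = np.where(
        (deg > deg_thr) & (btw > btw_thr),
        "major_hub",
        np.where((btw > btw_thr) & (deg < deg_thr), "connector", "none"),
    )
    out = metrics.copy()
    out["degree_threshold"] = deg_thr
    out["betweenness_threshold"] = btw_thr
    out["role"] = role
    return out


def modularity_of(net, partition: dict) -> float:
    """Direct Newman modularity Q of a given partition on the |rho|-weighted graph."""
    g = _unwrap(net)
    comms: dict = {}
    for node, mod in partition.items():
        comms.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(g, comms.values(), weight="weight"))


def detect_modules(net, resolution: float = 1.0, seed: int = 0, restarts: int = 10) -> tuple[dict, float]:
    """Louvain modules on the |rho|-weighted graph; best Q over seeded restarts.

    Returns (node -> module id, Q).  Module ids are relabeled by the
    smallest member node for stable output given a seed.
    """
    g = _unwrap(net)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    best_q, best_comms = -np.inf, None
    for r in range(max(restarts, 1)):
        comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed + r)
        q = float(nx.community.modularity(g, comms, weight="weight"))
        if q > best_q:
            best_q, best_comms = q, comms
    ordered = sorted(best_comms, key=lambda c: min(str(v) for v in c))
    partition = {node: i for i, comm in enumerate(ordered) for node in comm}
    return partition, best_q


def module_depth_profile(table: AbundanceTable, partition: dict) -> pd.DataFrame:
    """Mean per-module z-score profile across samples.

    Abundances are log1p-transformed, then standardized per gene with that
    gene's own mean and sd across all samples; a module's value in a sample
    is the arithmetic mean z of its member genes.  Zero-variance genes get
    z = 0 everywhere (logged).  Rows are module ids, columns samples.
    """
    if table.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    genes_by_module: dict = {}
    for gene, mod in partition.items():
        genes_by_module.setdefault(mod, []).append(gene)
    logv = np.log1p(table.values)
    mu = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance gene(s) assigned z=0 in module profiles", int(zero_var.sum()))
    sd = sd.replace(0, np.inf)
    z = logv.sub(mu, axis=0).div(sd, axis=0)
    rows = {}
    for mod, genes in sorted(genes_by_module.items(), key=lambda kv: str(kv[0])):
        present = [gn for gn in genes if gn in z.index]
        if not present:
            raise ValueError(f"module {mod!r} has no genes in the abundance table")
        rows[mod] = z.loc[present].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    return out


def hub_taxonomy_summary(hubs: pd.DataFrame, annotation: pd.DataFrame, table: AbundanceTable) -> pd.DataFrame:
    """Per-sample taxon shares of total hub-Fe-gene abundance.

    Hub Fe genes are those classified major_hub or connector whose cycle is
    Fe; shares sum to 1 per sample.  Returns an empty frame (with a
    warning) when the network has no Fe hubs.
    """
    hub_genes = [
        gn
        for gn in hubs.index[hubs["role"] != "none"]
        if gn in annotation.index and annotation.loc[gn, "cycle"] == "Fe" and gn in table.values.index
    ]
    if not hub_genes:
        logger.warning("no Fe hub genes; taxonomy summary is empty")
        return pd.DataFrame()
    taxa = annotation.loc[hub_genes, "taxon"]
    abund = table.values.loc[hub_genes]
    grouped = abund.groupby(taxa).sum()
    totals = grouped.sum(axis=0)
    shares = grouped.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    shares.index.name = "taxon"
    return shares
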