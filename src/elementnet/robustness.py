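"""Node-removal robustness: LCC-fraction curves and their AUC.

Nodes are removed one at a time, either uniformly at random (curves
averaged over replicates) or highest-current-degree-first (adaptive attack,
degrees recomputed after every removal, ties broken by node id).  After
each removal the size of the largest connected component is recorded as a
fraction of the ORIGINAL node count, so every curve ends at (1, 0); the
summary statistic is the trapezoidal area under the curve including the
endpoints (0, LCC0/N) and (1, 0).

Curves are evaluated efficiently by processing a removal order in reverse
as node additions with a union-find structure, so the whole curve costs
~O((N + E) alpha) per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

STRATEGIES = ("random", "targeted")


class _DSU:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return self.size[ra]
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return self.size[ra]


def _lcc_curve_for_order(adj: list[list[int]], order: list[int]) -> np.ndarray:
    """LCC size after each removal in `order` (prefix removals), via
    reverse addition.  Returns length N+1: [LCC(0 removed), ..., LCC(all)]."""
    n = len(adj)
    dsu = _DSU(n)
    active = [False] * n
    best = 0
    sizes_rev = [0]  # LCC with all nodes removed
    for node in reversed(order):
        active[node] = True
        best = max(best, 1)
        for nb in adj[node]:
            if active[nb]:
                best = max(best, dsu.union(node, nb))
        # union-by-size can merge without touching `best` root size; re-check
        best = max(best, dsu.size[dsu.find(node)])
        sizes_rev.append(best)
    return np.array(sizes_rev[::-1], dtype=float)


@dataclass
class RobustnessResult:
    strategy: str
    fractions_removed: np.ndarray
    lcc_fraction: np.ndarray  # mean over replicates
    lcc_se: np.ndarray  # standard error of the pointwise mean (0 for targeted)
    auc: float
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "fraction_removed": self.fractions_removed,
                "lcc_fraction": self.lcc_fraction,
                "se": self.lcc_se,
            }
        )


def _targeted_order(g: nx.Graph) -> list:
    """Highest-current-degree-first with stable node-id tie-break."""
    deg = dict(g.degree())
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    order = []
    remaining = set(g.nodes)
    while remaining:
        node = min(remaining, key=lambda v: (-deg[v], str(v)))
        order.append(node)
        remaining.remove(node)
        for nb in adj[node]:
            if nb in remaining:
                deg[nb] -= 1
                adj[nb].discard(node)
    return order


def removal_curve(net, strategy: str, seed: int = 0, replicates: int = 100) -> RobustnessResult:
    """LCC-fraction curve and AUC for one removal strategy.

    Targeted removal is deterministic up to ties (replicates forced to 1);
    random removal averages `replicates` uniformly shuffled orders.
    """
    g = net.graph if hasattr(net, "graph") and isinstance(net.graph, nx.Graph) else net
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    nodes = sorted(g.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[nb] for nb in g.neighbors(v)] for v in nodes]

    if strategy == "targeted":
        orders = [[index[v] for v in _targeted_order(g)]]
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(n)) for _ in range(replicates)]

    curves = np.stack([_lcc_curve_for_order(adj, order) / n for order in orders])
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(len(orders)) if len(orders) > 1 else np.zeros_like(mean)
    fracs = np.arange(n + 1) / n
    auc = float(np.trapezoid(mean, fracs))
    return RobustnessResult(
        strategy=strategy,
        fractions_removed=fracs,
        lcc_fraction=mean,
        lcc_se=se,
        auc=auc,
        replicates=len(orders),
        seed=seed,
    )


def compare_robustness(nets: dict, strategies=STRATEGIES, seed: int = 0, replicates: int = 100) -> pd.DataFrame:
    """One AUC per (network, strategy); deterministic for a fixed seed."""
    if not nets:
        raise ValueError("no networks supplied")
    rows = []
    for i, (name, net) in enumerate(sorted(nets.items(), key=lambda kv: str(kv[0]))):
        for strat in strategies:
            res = removal_curve(net, strat, seed=seed + i, replicates=replicates)
            rows.append({"network": name, "strategy": strat, "auc": res.auc, "replicates": res.replicates})
    return pd.DataFrame(rows)
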