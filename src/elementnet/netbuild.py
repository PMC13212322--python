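"""Bipartite Spearman co-occurrence networks with BH-FDR edge filtering.

Edges connect an Fe-metabolism gene to a gene of one target elemental cycle
(C, N, S or P); Fe-Fe and target-target pairs are never tested.  An edge is
retained when |rho| > rho_min AND BH-adjusted p (q) < q_max, both strict.

p-values: at the study's sample sizes (n = 6-7) the t approximation to the
Spearman null is badly anti-conservative, so for n <= 9 the two-sided
p-value is computed exactly by enumerating all n! pairings of the observed
(mid-)rank vectors.  The null distribution depends only on the two rank
multisets, so it is cached; with no ties there is a single cache entry per
n.  For n > 12 exact enumeration is refused.

Depth-controlled "residual networks" regress each gene's log1p abundance on
depth (OLS) and correlate the residuals, removing correlation induced by a
shared monotone depth gradient.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from elementnet.abundance import AbundanceTable, drop_zero_variance_genes, log1p_transform
from elementnet.config import TARGET_CYCLES

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12
EXACT_DEFAULT_MAX_N = 9
_FLOAT_TOL = 1e-9

_PERM_CACHE: dict[int, np.ndarray] = {}
_NULL_CACHE: dict[tuple, np.ndarray] = {}


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns NaN (with a warning) for constant input, which callers treat as
    an undefined, skipped pair.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        logger.warning("constant vector in spearman_rho; correlation undefined")
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    return float(cx @ cy / np.sqrt((cx @ cx) * (cy @ cy)))


def _permutations(n: int) -> np.ndarray:
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    return _PERM_CACHE[n]


def _null_abs_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> np.ndarray:
    """Sorted |rho| over all n! pairings of the two rank multisets."""
    sig_x = tuple(np.sort(x_ranks))
    sig_y = tuple(np.sort(y_ranks))
    key = (sig_x, sig_y) if sig_x <= sig_y else (sig_y, sig_x)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    xr = np.array(key[0], float)
    yr = np.array(key[1], float)
    n = len(xr)
    cx = xr - xr.mean()
    cy = yr - yr.mean()
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    perms = _permutations(n)
    rhos = (cy[perms] @ cx) / denom
    null = np.sort(np.abs(rhos))
    _NULL_CACHE[key] = null
    return null


def _exact_p(rho: float, x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    null = _null_abs_rho(x_ranks, y_ranks)
    count = len(null) - np.searchsorted(null, abs(rho) - _FLOAT_TOL, side="left")
    return float(count) / len(null)


def _t_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return float(2.0 * stats.t.sf(np.inf, n - 2) + np.finfo(float).tiny)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_pvalue(rho: float, n: int, method: str = "exact", ranks: tuple | None = None) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    ``method="exact"`` enumerates all n! rank pairings (proportion of
    permutations with |rho_perm| >= |rho_obs|); refuses n > 12.  Pass
    ``ranks=(x_ranks, y_ranks)`` to permute observed tied mid-ranks;
    untied ranks 1..n are assumed otherwise.  ``method="t"`` uses the
    t approximation with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if math.isnan(rho):
        return float("nan")
    if method == "t":
        return _t_p(rho, n)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > EXACT_MAX_N:
        raise ValueError(f"exact enumeration refused for n={n} > {EXACT_MAX_N} (factorial blow-up)")
    if ranks is None:
        base = np.arange(1.0, n + 1.0)
        return _exact_p(rho, base, base)
    return _exact_p(rho, np.asarray(ranks[0], float), np.asarray(ranks[1], float))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q), input order kept."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CooccurrenceNetwork:
    """Undirected signed weighted bipartite Fe-vs-target co-occurrence graph.

    Node attributes: ``cycle``, ``category``, ``taxon``.  Edge attributes:
    ``rho``, ``q``, ``weight`` (= |rho|), ``sign``.
    """

    graph: nx.Graph
    target_cycle: str
    edges: pd.DataFrame = field(repr=False)
    rho_min: float = 0.7
    q_max: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _resolve_method(method: str, n: int) -> str:
    if method == "auto":
        return "exact" if n <= EXACT_DEFAULT_MAX_N else "t"
    return method


def correlate_bipartite(
    table: AbundanceTable,
    annotation: pd.DataFrame,
    target_cycle: str,
    method: str = "auto",
) -> pd.DataFrame:
    """All Fe x target-cycle Spearman correlations with BH-adjusted q.

    Returns a DataFrame with columns ``fe_gene, target_gene, rho, p, q``;
    one row per unordered cross-cycle pair.  BH is applied over all tested
    pairs of this network (per target cycle, not pooled across cycles).
    Constant-abundance genes are skipped with a warning.
    """
    if target_cycle not in TARGET_CYCLES:
        raise ValueError(f"target_cycle must be one of {TARGET_CYCLES}, got {target_cycle!r}")
    table = drop_zero_variance_genes(table)
    vals = table.values
    cycles = annotation["cycle"].reindex(vals.index)
    fe_genes = list(vals.index[cycles == "Fe"])
    tg_genes = list(vals.index[cycles == target_cycle])
    n = vals.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not fe_genes or not tg_genes:
        raise ValueError(f"no testable Fe x {target_cycle} pairs (need >=1 non-constant gene on each side)")
    use = _resolve_method(method, n)

    def ranks_of(genes):
        m = vals.loc[genes].to_numpy(float)
        r = np.apply_along_axis(stats.rankdata, 1, m)
        c = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((c * c).sum(axis=1))
        return r, c / norm[:, None]

    fe_r, fe_n = ranks_of(fe_genes)
    tg_r, tg_n = ranks_of(tg_genes)
    rho = fe_n @ tg_n.T  # len(fe) x len(tg)

    fe_idx, tg_idx = np.meshgrid(np.arange(len(fe_genes)), np.arange(len(tg_genes)), indexing="ij")
    fe_idx, tg_idx = fe_idx.ravel(), tg_idx.ravel()
    rho_flat = np.clip(rho.ravel(), -1.0, 1.0)

    if use == "t":
        p = np.array([_t_p(r, n) for r in rho_flat])
    else:
        if n > EXACT_MAX_N:
            raise ValueError(f"exact enumeration refused for n={n} > {EXACT_MAX_N}")
        # Group pairs by the (x multiset, y multiset) cache key and use one
        # sorted null per group: vastly faster than per-pair enumeration.
        fe_sig = [tuple(np.sort(row)) for row in fe_r]
        tg_sig = [tuple(np.sort(row)) for row in tg_r]
        p = np.empty(len(rho_flat))
        keys = {}
        for k, (i, j) in enumerate(zip(fe_idx, tg_idx)):
            a, b = fe_sig[i], tg_sig[j]
            key = (a, b) if a <= b else (b, a)
            keys.setdefault(key, []).append(k)
        for key, members in keys.items():
            null = _null_abs_rho(np.array(key[0]), np.array(key[1]))
            obs = np.abs(rho_flat[members])
            cnt = len(null) - np.searchsorted(null, obs - _FLOAT_TOL, side="left")
            p[members] = cnt / len(null)

    out = pd.DataFrame(
        {
            "fe_gene": [fe_genes[i] for i in fe_idx],
            "target_gene": [tg_genes[j] for j in tg_idx],
            "rho": rho_flat,
            "p": p,
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["n_samples"] = n
    out.attrs["p_method"] = use
    out.attrs["target_cycle"] = target_cycle
    return out


def build_network(
    correlations: pd.DataFrame,
    annotation: pd.DataFrame,
    target_cycle: str | None = None,
    rho_min: float = 0.7,
    q_max: float = 0.01,
) -> CooccurrenceNetwork:
    """Threshold correlations into a co-occurrence network.

    Edge rule (both strict): |rho| > rho_min AND q < q_max.  Nodes are the
    genes incident to at least one retained edge; an empty network is
    allowed and logged.
    """
    if not (0.0 < rho_min < 1.0) or not (0.0 < q_max < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    target_cycle = target_cycle or correlations.attrs.get("target_cycle", "?")
    keep = correlations[(correlations["rho"].abs() > rho_min) & (correlations["q"] < q_max)].copy()
    g = nx.Graph()
    for row in keep.itertuples(index=False):
        g.add_edge(
            row.fe_gene,
            row.target_gene,
            rho=float(row.rho),
            q=float(row.q),
            weight=float(abs(row.rho)),
            sign=int(np.sign(row.rho)),
        )
    for node in g.nodes:
        if node in annotation.index:
            g.nodes[node]["cycle"] = str(annotation.loc[node, "cycle"])
            g.nodes[node]["category"] = str(annotation.loc[node, "category"])
            if "taxon" in annotation.columns:
                g.nodes[node]["taxon"] = str(annotation.loc[node, "taxon"])
    if g.number_of_edges() == 0:
        logger.warning("network Fe-%s is empty at |rho|>%g, q<%g", target_cycle, rho_min, q_max)
    return CooccurrenceNetwork(graph=g, target_cycle=target_cycle, edges=keep, rho_min=rho_min, q_max=q_max)


@dataclass
class ResidualTable:
    """Per-gene OLS residuals of log1p(RPM) on depth, plus fit parameters."""

    residuals: pd.DataFrame
    slopes: pd.Series
    intercepts: pd.Series


def residual_table(table: AbundanceTable, depths=None) -> ResidualTable:
    """Regress each gene's log1p abundance on sediment depth (OLS with
    intercept) and return the residual matrix.  Residuals per gene sum to 0."""
    depths = np.asarray(table.depths() if depths is None else depths, float)
    if len(depths) != table.values.shape[1]:
        raise ValueError("depth vector length does not match sample count")
    if len(depths) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(depths) == 0:
        raise ValueError("constant depth vector; residual regression undefined")
    y = np.log1p(table.values.to_numpy(float))
    x = depths - depths.mean()
    sxx = float(x @ x)
    slopes = (y @ x) / sxx
    intercepts = y.mean(axis=1)
    resid = y - intercepts[:, None] - slopes[:, None] * x[None, :]
    idx = table.values.index
    return ResidualTable(
        residuals=pd.DataFrame(resid, index=idx, columns=table.values.columns),
        slopes=pd.Series(slopes, index=idx),
        intercepts=pd.Series(intercepts - slopes * depths.mean(), index=idx),
    )


def residual_network(
    table: AbundanceTable,
    annotation: pd.DataFrame,
    target_cycle: str,
    rho_min: float = 0.7,
    q_max: float = 0.01,
    method: str = "auto",
    depths=None,
    var_floor: float = 1e-12,
) -> CooccurrenceNetwork:
    """Depth-controlled residual co-occurrence network.

    log1p(RPM) is regressed on depth per gene; Spearman correlations are
    computed on the residuals.  Genes whose residual variance falls below
    ``var_floor`` (abundance exactly linear in depth) are dropped with a
    warning.
    """
    res = residual_table(table, depths=depths)
    variances = res.residuals.var(axis=1, ddof=0)
    keep = variances >= var_floor
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d gene(s) with ~zero residual variance", dropped)
    resid_table = AbundanceTable(res.residuals.loc[keep], table.sample_meta)
    cors = correlate_bipartite(resid_table, annotation, target_cycle, method=method)
    return build_network(cors, annotation, target_cycle, rho_min=rho_min, q_max=q_max)
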