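"""Unit and oracle tests for Spearman correlation, exact permutation
p-values, BH adjustment, network thresholding and residual networks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import elementnet as en
from elementnet.netbuild import residual_table, spearman_pvalue, spearman_rho
from tests.conftest import make_annotation, make_table

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)


def _midranks(v):
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _rho_oracle(x, y):
    rx, ry = _midranks(x), _midranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def _exact_p_oracle(x, y):
    rho_obs = abs(_rho_oracle(x, y))
    ry = _midranks(y)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rho_oracle(_midranks(x), list(perm))) >= rho_obs - 1e-9:
            count += 1
    return count / total


def _bh_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------


class TestSpearmanRho:
    def test_perfect_concordance_and_discordance(self):
        assert spearman_rho([1, 5, 9, 12], [0.1, 0.2, 0.3, 4.0]) == pytest.approx(1.0)
        assert spearman_rho([1, 5, 9, 12], [4.0, 0.3, 0.2, 0.1]) == pytest.approx(-1.0)

    def test_three_point_hand_value(self):
        assert spearman_rho([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_is_nan(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_oracle_and_scipy_with_ties(self, n, rng):
        for _ in range(30):
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if len(np.unique(x)) < 2:
                continue
            got = spearman_rho(x, y)
            assert got == pytest.approx(_rho_oracle(x, y))
            assert got == pytest.approx(stats.spearmanr(x, y).statistic)


class TestExactPValue:
    def test_small_n_closed_forms(self):
        assert spearman_pvalue(1.0, 3) == pytest.approx(2 / 6)
        assert spearman_pvalue(1.0, 7) == pytest.approx(2 / 5040)
        assert spearman_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="factorial"):
            spearman_pvalue(0.5, 13, method="exact")

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(10):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho = spearman_rho(x, y)
            got = spearman_pvalue(rho, n, method="exact")
            assert got == pytest.approx(_exact_p_oracle(list(x), list(y)))

    @pytest.mark.parametrize("n", [5, 6])
    def test_matches_enumeration_oracle_with_ties(self, n, rng):
        for _ in range(8):
            x = rng.integers(0, 3, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            rho = spearman_rho(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            got = spearman_pvalue(rho, n, method="exact", ranks=(rx, ry))
            assert got == pytest.approx(_exact_p_oracle(list(x), list(y)))

    def test_t_method_is_anticonservative_at_small_n(self):
        # the motivation for exact enumeration at the study's sample sizes
        assert spearman_pvalue(1.0, 6, method="t") < spearman_pvalue(1.0, 6, method="exact")


class TestBH:
    def test_hand_example_and_identity(self):
        assert np.allclose(en.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(en.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_stepup_oracle(self, rng):
        for m in (1, 5, 50):
            p = rng.uniform(1e-6, 1, size=m)
            assert np.allclose(en.bh_adjust(p), _bh_oracle(list(p)))

    def test_sorted_q_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(1e-6, 1, size=40))
        q = en.bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            en.bh_adjust([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_stepup_property(self, p):
        q = en.bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p))
        assert (q <= 1.0 + 1e-12).all()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rho_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 6))
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(np.exp(x), y**3))


def _bipartite_setup(x_fe, x_tg, depths=None):
    values = np.vstack([x_fe, x_tg])
    genes = [f"fe{i}" for i in range(len(x_fe))] + [f"tg{i}" for i in range(len(x_tg))]
    table = make_table(values, gene_ids=genes, depths=depths)
    ann = make_annotation({g: ("Fe" if g.startswith("fe") else "C") for g in genes})
    return table, ann


class TestCorrelateBipartite:
    def test_pair_combinatorics_and_bipartite_contract(self, rng):
        table, ann = _bipartite_setup(rng.normal(size=(2, 6)), rng.normal(size=(3, 6)))
        cors = en.correlate_bipartite(table, ann, "C")
        assert len(cors) == 6
        assert set(cors.fe_gene).issubset({"fe0", "fe1"})
        assert set(cors.target_gene).issubset({"tg0", "tg1", "tg2"})

    def test_planted_monotone_pair_hits_p_floor(self):
        base = np.arange(7.0)
        table, ann = _bipartite_setup([base], [base * 2 + 1])
        cors = en.correlate_bipartite(table, ann, "C")
        assert cors.rho.iloc[0] == pytest.approx(1.0)
        assert cors.p.iloc[0] == pytest.approx(2 / 5040)

    def test_matches_per_pair_oracle(self, rng):
        table, ann = _bipartite_setup(rng.normal(size=(4, 6)), rng.normal(size=(6, 6)))
        cors = en.correlate_bipartite(table, ann, "C")
        for row in cors.sample(8, random_state=0).itertuples():
            x = table.values.loc[row.fe_gene].to_numpy()
            y = table.values.loc[row.target_gene].to_numpy()
            assert row.rho == pytest.approx(_rho_oracle(x, y))
            assert row.p == pytest.approx(_exact_p_oracle(list(x), list(y)))

    def test_edge_set_invariant_under_monotone_transform(self, rng):
        table, ann = _bipartite_setup(rng.normal(size=(5, 7)), rng.normal(size=(8, 7)))
        net1 = en.build_network(en.correlate_bipartite(table, ann, "C"), ann, "C", rho_min=0.5, q_max=0.9)
        warped = make_table(np.exp(table.values.to_numpy() / 2.0), gene_ids=table.gene_ids)
        net2 = en.build_network(en.correlate_bipartite(warped, ann, "C"), ann, "C", rho_min=0.5, q_max=0.9)
        assert set(net1.graph.edges) == set(net2.graph.edges)


class TestBuildNetwork:
    def _cors(self, rows):
        df = pd.DataFrame(rows, columns=["fe_gene", "target_gene", "rho", "p", "q"])
        return df

    def test_strict_thresholds(self):
        ann = make_annotation({"a": "Fe", "b": "C", "c": "C"})
        cors = self._cors([("a", "b", 0.71, 0.001, 0.005), ("a", "c", 0.70, 0.001, 0.005)])
        net = en.build_network(cors, ann, "C")
        assert net.graph.has_edge("a", "b")
        assert not net.graph.has_edge("a", "c")  # rho == 0.70 excluded by strict >

    def test_every_node_has_degree_and_sign_kept(self):
        ann = make_annotation({"a": "Fe", "b": "C"})
        net = en.build_network(self._cors([("a", "b", -0.9, 0.001, 0.001)]), ann, "C")
        assert net.graph.edges["a", "b"]["sign"] == -1
        assert net.graph.edges["a", "b"]["weight"] == pytest.approx(0.9)
        assert min(dict(net.graph.degree).values()) >= 1

    def test_threshold_monotonicity(self, rng):
        table, ann = _bipartite_setup(rng.normal(size=(5, 7)), rng.normal(size=(8, 7)))
        cors = en.correlate_bipartite(table, ann, "C")
        loose = en.build_network(cors, ann, "C", rho_min=0.3, q_max=0.9)
        tight_rho = en.build_network(cors, ann, "C", rho_min=0.6, q_max=0.9)
        tight_q = en.build_network(cors, ann, "C", rho_min=0.3, q_max=0.5)
        assert set(tight_rho.graph.edges) <= set(loose.graph.edges)
        assert set(tight_q.graph.edges) <= set(loose.graph.edges)

    def test_complete_bipartite_from_planted_block(self):
        base = np.arange(7.0)
        table, ann = _bipartite_setup([base, base + 3, -base], [base * 2, 5 - base, base / 2])
        net = en.build_network(en.correlate_bipartite(table, ann, "C"), ann, "C")
        assert net.n_nodes == 6
        assert net.n_edges == 9  # complete bipartite 3x3


class TestResidualNetworks:
    def test_residuals_sum_to_zero_and_slopes_recovered(self):
        depths = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0])
        vals = np.vstack([np.expm1(0.3 * depths + 1.0), np.expm1(-0.1 * depths + 5.0)])
        table = make_table(vals, depths=depths)
        res = residual_table(table)
        assert np.allclose(res.residuals.sum(axis=1), 0.0, atol=1e-9)
        assert res.slopes.iloc[0] == pytest.approx(0.3)
        assert res.slopes.iloc[1] == pytest.approx(-0.1)

    def test_exactly_linear_gene_dropped(self, rng):
        depths = np.arange(2.0, 30.0, 4.0)
        linear = np.expm1(0.2 * depths)
        other_fe = np.exp(rng.normal(size=7))
        noisy = np.exp(rng.normal(size=(3, 7)))
        table, ann = _bipartite_setup([linear, other_fe], noisy, depths=depths)
        net = en.residual_network(table, ann, "C", rho_min=0.5, q_max=0.99)
        assert "fe0" not in net.graph.nodes

    def test_shared_trend_eliminated(self, rng):
        # two genes riding the same depth gradient correlate strongly raw,
        # but their residuals are independent
        depths = np.arange(2.0, 30.0, 4.0)
        raw_hits, resid_hits = 0, 0
        n_rep = 60
        for _ in range(n_rep):
            a = np.exp(0.25 * depths + rng.normal(0, 0.3, 7))
            b = np.exp(0.25 * depths + rng.normal(0, 0.3, 7))
            table, ann = _bipartite_setup([a], [b], depths=depths)
            cors = en.correlate_bipartite(table, ann, "C")
            if abs(cors.rho.iloc[0]) > 0.7:
                raw_hits += 1
            rnet = en.residual_network(table, ann, "C")
            resid_hits += rnet.n_edges
        assert raw_hits / n_rep > 0.5
        assert resid_hits / max(raw_hits, 1) < 0.2

    def test_constant_depths_rejected(self, rng):
        table, ann = _bipartite_setup(rng.normal(size=(1, 5)) ** 2, rng.normal(size=(1, 5)) ** 2)
        with pytest.raises(ValueError, match="depth"):
            en.residual_network(table, ann, "C", depths=np.ones(5))
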