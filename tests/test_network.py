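"""Correlation networks, centralities, and cohort comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from becseq.network import (
    CorrelationNetwork,
    centrality,
    compare_networks,
    fisher_r_to_z,
    pearson_edges,
    _wilcoxon_rank_sum,
)
from becseq.quantify import AbundanceMatrix, MEASURED


def matrix_from(values: np.ndarray, assays=None) -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    assays = assays or [f"A{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(values.shape[0])],
                      columns=assays)
    return AbundanceMatrix(df, pd.DataFrame(MEASURED, index=df.index,
                                            columns=df.columns))


def exact_correlated(r: float, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors with exact sample correlation r (Gram-Schmidt)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y


class TestPearsonEdges:
    def test_exact_proportionality_gives_edge(self, rng):
        x = rng.gamma(3, 100, 10)
        mat = matrix_from(np.column_stack([x, 2 * x]))
        net = pearson_edges(mat, log_transform=False)
        assert net.n_edges == 1
        assert net.edges["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_pair_has_no_edge(self, rng):
        x, y = exact_correlated(0.0, 10, rng)
        net = pearson_edges(matrix_from(np.column_stack([x + 10, y + 10])),
                            log_transform=False)
        assert net.n_edges == 0

    def test_boundary_behavior_is_strict_inequality(self, rng):
        """n=10: the p<0.05 cut falls at r* = 2.3060/sqrt(8+2.3060^2) ~ 0.6319.

        t = r*sqrt(8/(1-r^2)) is 2.3066 at r=0.632 (p=0.049951, just under
        0.05, edge kept); at r=0.6310 the p is just above 0.05 and the edge
        is dropped by the strict inequality.
        """
        x, y = exact_correlated(0.632, 10, rng)
        mat = matrix_from(np.column_stack([x + 10, y + 10]))
        t = 0.632 * np.sqrt(8 / (1 - 0.632**2))
        assert t == pytest.approx(2.3066, abs=1e-3)
        assert 2 * stats.t.sf(t, 8) == pytest.approx(0.049951, abs=1e-5)
        assert pearson_edges(mat, log_transform=False).n_edges == 1
        x2, y2 = exact_correlated(0.6310, 10, rng)
        mat2 = matrix_from(np.column_stack([x2 + 10, y2 + 10]))
        assert pearson_edges(mat2, log_transform=False).n_edges == 0

    def test_edges_match_t_inversion_oracle(self, rng):
        vals = np.exp(rng.normal(size=(12, 6)))
        mat = matrix_from(vals)
        net = pearson_edges(mat, alpha=0.05, log_transform=True)
        got = {frozenset(e) for e in zip(net.edges["assay_a"], net.edges["assay_b"])}
        want = set()
        logs = np.log10(vals)
        for i, j in itertools.combinations(range(6), 2):
            r = np.corrcoef(logs[:, i], logs[:, j])[0, 1]
            t = r * np.sqrt(10 / (1 - r * r))
            if 2 * stats.t.sf(abs(t), 10) < 0.05:
                want.add(frozenset({f"A{i}", f"A{j}"}))
        assert got == want

    def test_affine_rescaling_keeps_edge_set(self, rng):
        vals = np.exp(rng.normal(size=(15, 5)))
        base = pearson_edges(matrix_from(vals), log_transform=False)
        scaled = vals * np.array([3.0, 0.5, 7.0, 1.0, 100.0])
        again = pearson_edges(matrix_from(scaled), log_transform=False)
        e1 = {frozenset(e) for e in zip(base.edges["assay_a"], base.edges["assay_b"])}
        e2 = {frozenset(e) for e in zip(again.edges["assay_a"], again.edges["assay_b"])}
        assert e1 == e2

    def test_constant_column_isolated_with_warning(self, rng):
        vals = np.column_stack([rng.normal(10, 1, 10), np.full(10, 5.0)])
        with pytest.warns(UserWarning, match="isolated"):
            net = pearson_edges(matrix_from(vals), log_transform=False)
        assert net.n_edges == 0

    def test_pairwise_complete_uses_shared_subjects(self, rng):
        x = rng.normal(10, 1, 20)
        y = 2 * x + rng.normal(0, 0.01, 20)
        y[:5] = np.nan
        vals = pd.DataFrame({"A0": x, "A1": y},
                            index=[f"S{i}" for i in range(20)])
        mat = AbundanceMatrix(vals, pd.DataFrame(MEASURED, index=vals.index,
                                                 columns=vals.columns))
        net = pearson_edges(mat, log_transform=False)
        assert net.edges["n"].iloc[0] == 15


def bfs_centralities(edges: set[frozenset], nodes: list[str]):
    """Brute-force shortest-path centralities by BFS path enumeration."""
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        if s == t:
            return []
        paths, frontier = [], [[s]]
        found_len = None
        while frontier and found_len is None:
            nxt = []
            for path in frontier:
                for w in adj[path[-1]]:
                    if w in path:
                        continue
                    if w == t:
                        paths.append(path + [w])
                    else:
                        nxt.append(path + [w])
            if paths:
                found_len = len(paths[0])
            frontier = nxt
        return paths

    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}
    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            betweenness[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2
    betweenness = {v: b / scale for v, b in betweenness.items()}
    for v in nodes:
        total = 0.0
        for u in nodes:
            if u == v:
                continue
            paths = all_shortest_paths(v, u)
            if paths:
                total += 1.0 / (len(paths[0]) - 1)
        closeness[v] = total / (n - 1)
    return degree, betweenness, closeness


class TestCentrality:
    def make_net(self, nodes, edge_pairs):
        edges = pd.DataFrame(
            [(a, b, 0.9, 0.01, 10) for a, b in edge_pairs],
            columns=["assay_a", "assay_b", "r", "p", "n"],
        )
        return CorrelationNetwork(nodes, edges, alpha=0.05)

    def test_path_graph(self):
        net = self.make_net(["A", "B", "C"], [("A", "B"), ("B", "C")])
        m = centrality(net)
        assert m["degree"].tolist() == [1, 2, 1]
        assert m.loc["B", "betweenness"] == pytest.approx(1.0)
        assert m.loc["A", "betweenness"] == 0.0
        # closeness: A reaches B at 1, C at 2 -> (1 + 1/2)/2 = 0.75
        assert m.loc["A", "closeness"] == pytest.approx(0.75)
        assert m.loc["B", "closeness"] == pytest.approx(1.0)

    def test_complete_graph(self):
        nodes = ["A", "B", "C", "D"]
        net = self.make_net(nodes, list(itertools.combinations(nodes, 2)))
        m = centrality(net)
        assert (m["betweenness"] == 0).all()
        assert (m["closeness"] == 1.0).all()

    def test_isolated_node_contributes_zero(self):
        net = self.make_net(["A", "B", "C"], [("A", "B")])
        m = centrality(net)
        assert m.loc["C", "degree"] == 0
        assert m.loc["C", "closeness"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_bfs_oracle(self, seed):
        r = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(8)]
        edge_pairs = [
            (a, b) for a, b in itertools.combinations(nodes, 2)
            if r.random() < 0.35
        ]
        net = self.make_net(nodes, edge_pairs)
        m = centrality(net)
        deg, btw, clo = bfs_centralities(
            {frozenset(e) for e in edge_pairs}, nodes
        )
        for v in nodes:
            assert m.loc[v, "degree"] == deg[v]
            assert m.loc[v, "betweenness"] == pytest.approx(btw[v], abs=1e-12)
            assert m.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)


def enumerate_rank_sum_p(x, y):
    """Exact two-sided p by full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    n = len(pooled)
    ws = [
        sum(ranks[list(c)])
        for c in itertools.combinations(range(n), len(x))
    ]
    ws = np.array(ws)
    mean_w = ws.mean()
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return float(p)


class TestCompareNetworks:
    def metrics(self, values):
        return pd.DataFrame(
            {"degree": values, "betweenness": values, "closeness": values},
            index=[f"N{i}" for i in range(len(values))],
        )

    def test_identical_metrics_p_one(self):
        m = self.metrics([1, 2, 3, 4])
        out = compare_networks(m, m.copy())
        assert (out["p"] == 1.0).all()

    def test_disjoint_small_groups_exact(self):
        # (1,2,3) vs (4,5,6): one-sided tail 1/20 -> two-sided 0.1
        _, p = _wilcoxon_rank_sum(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert p == pytest.approx(0.1, rel=1e-12)
        _, p4 = _wilcoxon_rank_sum(
            np.array([1, 2, 3, 4]), np.array([10, 11, 12, 13])
        )
        assert p4 == pytest.approx(2 / 70, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_full_enumeration(self, seed):
        r = np.random.default_rng(seed)
        x = r.permutation(np.arange(1.0, 13.0))[:6]
        rest = np.setdiff1d(np.arange(1.0, 13.0), x)
        y = rest[:6]
        _, p = _wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(enumerate_rank_sum_p(x, y), rel=1e-9)

    def test_node_universe_mismatch_rejected(self):
        a = self.metrics([1, 2, 3])
        b = self.metrics([1, 2, 3, 4])
        with pytest.raises(ValueError):
            compare_networks(a, b)


class TestFisherRtoZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_r_to_z(0.4, 30, 0.4, 50)
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        # atanh(0.8)=1.0986, SE=sqrt(2/27)=0.2722 -> z=4.0365
        z, p = fisher_r_to_z(0.8, 30, 0.0, 30)
        assert z == pytest.approx(4.0365, abs=2e-4)
        assert p == pytest.approx(5.44e-5, rel=1e-2)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z(0.7, 25, 0.2, 40)
        z2, p2 = fisher_r_to_z(0.2, 40, 0.7, 25)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 30, 0.5, 30)


class TestCohortComparison:
    def test_copd_network_denser_with_planted_wiring(self, study):
        """The planted pathway factor makes the COPD network denser."""
        assert study.networks["COPD"].n_edges > study.networks["control"].n_edges
        comp = study.network_comparison
        assert comp.loc["degree", "p"] < 0.05
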