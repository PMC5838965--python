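"""Per-cohort Pearson co-expression networks and their comparison.

Nodes are assays; an undirected edge joins two assays whose log10
abundances correlate with two-sided p < alpha within a cohort (no
multiple-testing correction on the edge filter — the network is a
descriptive summary, not an inference).  Cohort topology is compared by
Wilcoxon rank-sum tests on per-node degree, betweenness and harmonic
closeness, and individual gene-pair correlations are compared between
cohorts with the Fisher r-to-z test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceMatrix

__all__ = [
    "CorrelationNetwork",
    "pearson_edges",
    "centrality",
    "compare_networks",
    "fisher_r_to_z",
]


@dataclass
class CorrelationNetwork:
    """Assay graph with Pearson-r edges significant at the build alpha."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: assay_a, assay_b, r, p, n
    alpha: float
    graph: nx.Graph = field(init=False)

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.assay_a, row.assay_b, r=row.r, p=row.p, n=row.n)
        self.graph = g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-sided p on pairwise-complete observations.

    p comes from t = r * sqrt((n-2) / (1 - r^2)) on n-2 df.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 4:
        return float("nan"), float("nan"), n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(xs, ys)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_edges(
    matrix: AbundanceMatrix,
    subjects: list[str] | None = None,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> CorrelationNetwork:
    """Build one cohort's correlation network.

    ``subjects`` restricts the matrix to a cohort.  With ``log_transform``
    (default) abundances are log10-transformed first; non-positive values
    are treated as missing since a zero abundance means the transcript was
    undetected, not that its log is defined.  Correlations use
    pairwise-complete observations; constant or all-missing columns leave
    their node isolated with a warning.
    """
    values = matrix.values
    if subjects is not None:
        values = values.loc[subjects]
    if log_transform:
        values = values.where(values > 0)
        values = np.log10(values)
    cols = list(values.columns)
    arr = values.to_numpy(dtype=float)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r, p, n = _pairwise_pearson(arr[:, i], arr[:, j])
            if np.isnan(r):
                continue
            if p < alpha:
                rows.append((cols[i], cols[j], r, p, n))
    degenerate = [c for k, c in enumerate(cols) if np.nanstd(arr[:, k]) == 0]
    if degenerate:
        warnings.warn(
            f"constant/empty columns left isolated: {degenerate}", stacklevel=2
        )
    edges = pd.DataFrame(rows, columns=["assay_a", "assay_b", "r", "p", "n"])
    return CorrelationNetwork(cols, edges, alpha)


def centrality(network: CorrelationNetwork) -> pd.DataFrame:
    """Degree, normalized betweenness, and normalized harmonic closeness.

    Harmonic closeness (mean of 1/d over all other nodes) is used because
    significance-thresholded correlation graphs are routinely disconnected,
    where classic closeness is undefined.  Betweenness is normalized by
    (n-1)(n-2)/2; both centralities are 0 for isolated nodes and at most 1.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("network has no nodes")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    harmonic = nx.harmonic_centrality(g)
    scale = (n - 1) if n > 1 else 1
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in network.nodes],
            "betweenness": [betweenness[v] for v in network.nodes],
            "closeness": [harmonic[v] / scale for v in network.nodes],
        },
        index=pd.Index(network.nodes, name="assay"),
    )


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the pooled sample is small (<= 20) and
    tie-free; otherwise normal approximation with tie and continuity
    corrections.  Returns (W, p) with W the rank-sum statistic of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(stats.rankdata(pooled)[: x.size].sum()), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def compare_networks(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of node-metric distributions.

    Both tables must cover the same node universe (the comparison is of
    topologies over a common gene panel, not of different panels).
    """
    if set(metrics_a.index) != set(metrics_b.index):
        raise ValueError("node universes differ between the two metric tables")
    rows = {}
    for metric in ("degree", "betweenness", "closeness"):
        w, p = _wilcoxon_rank_sum(
            metrics_a[metric].to_numpy(), metrics_b[metric].to_numpy()
        )
        rows[metric] = {"W": w, "p": p}
    return pd.DataFrame(rows).T


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than 3 subjects per group")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| = 1 has infinite Fisher transform")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2 * float(stats.norm.sf(abs(z)))
    return float(z), p
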