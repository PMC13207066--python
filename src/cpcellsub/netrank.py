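"""Critical-gene prioritization in a regulatory network.

Five node centralities — degree, betweenness, eigenvector, PageRank, and
(harmonic) closeness — are each converted to a rank ratio r_i in (0, 1]
(rank among nodes divided by node count, best = smallest), and the five
ratios are fused with the joint order-statistic Q statistic:

    Q(r_1 <= ... <= r_N) = N! * V_N,
    V_k = sum_{j=1..k} (-1)^(j-1) * V_{k-j} / j! * r_{N-k+1}^j,

with V_0 = 1 and r_0 = 0. Q equals the probability that the order
statistics of N independent Uniform(0,1) variables fall jointly below the
given rank ratios, so a small Q flags a gene ranked consistently near the
top across all centrality indices. The top fraction (default 1%) of genes
by ascending Q are reported as critical genes.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .data_model import Network

logger = logging.getLogger(__name__)

__all__ = [
    "CENTRALITY_INDICES",
    "compute_centralities",
    "q_fuse",
    "add_q_statistic",
    "select_critical",
    "rank_network",
]

CENTRALITY_INDICES = ("degree", "betweenness", "eigenvector", "pagerank", "closeness")


def _to_graphs(net: Network) -> tuple[nx.Graph, nx.DiGraph]:
    directed = nx.DiGraph()
    directed.add_weighted_edges_from(net.edges)
    return directed.to_undirected(), directed


def compute_centralities(
    net: Network, *, directed_all: bool = False, max_iter: int = 1000
) -> pd.DataFrame:
    """Five centrality indices per node.

    Degree, betweenness, eigenvector and closeness are computed on the
    undirected view (regulatory edge direction makes path-based indices
    mostly zero on sparse TF->target graphs); PageRank uses the directed
    view with damping 0.85 and uniform teleport. ``directed_all`` switches
    every index to the directed view. Closeness is the harmonic variant so
    disconnected graphs are well defined.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    und, dirg = _to_graphs(net)
    g = dirg if directed_all else und
    # eigenvector centrality per connected component: on disconnected
    # graphs the global power iteration is ill-posed (competing leading
    # eigenvalues), so each component gets its own unit-norm vector
    eig: dict = {}
    und_view = g.to_undirected() if g.is_directed() else g
    for comp in nx.connected_components(und_view):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            eig.update({n: 0.0 for n in comp})
            continue
        try:
            eig.update(nx.eigenvector_centrality(sub, max_iter=max_iter, tol=1e-8))
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                f"eigenvector centrality failed to converge in {max_iter} "
                f"iterations (component of {len(comp)} nodes)"
            ) from exc
    pr_graph = dirg if net.directed else und
    table = pd.DataFrame(
        {
            "degree": dict(nx.degree_centrality(g)),
            "betweenness": nx.betweenness_centrality(g, normalized=True),
            "eigenvector": eig,
            "pagerank": nx.pagerank(pr_graph, alpha=0.85),
            "closeness": nx.harmonic_centrality(g),
        }
    )
    return table.sort_index()


def q_fuse(rank_ratios: list[float] | np.ndarray) -> float:
    """Fuse sorted rank ratios into the joint order-statistic Q in (0, 1].

    Input is sorted ascending defensively (with a log message if it was
    not already sorted); every ratio must lie in (0, 1]. Q(1, ..., 1) = 1
    and Q is monotone non-decreasing in each ratio.
    """
    r = np.asarray(rank_ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank-ratio list")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("rank ratios must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        logger.debug("rank ratios were unsorted; sorting ascending")
        r = np.sort(r)
    n = r.size
    v = np.zeros(n + 1)
    v[0] = 1.0
    for k in range(1, n + 1):
        s = 0.0
        for j in range(1, k + 1):
            s += (-1) ** (j - 1) * v[k - j] / math.factorial(j) * r[n - k] ** j
        v[k] = s
    return float(math.factorial(n) * v[n])


def _rank_ratios(values: pd.Series) -> pd.Series:
    """Average-rank ratio, centrality descending (best = smallest ratio)."""
    ranks = scipy.stats.rankdata(-values.to_numpy())
    return pd.Series(ranks / len(values), index=values.index)


def add_q_statistic(centralities: pd.DataFrame) -> pd.DataFrame:
    """Append per-index rank ratios, the fused Q statistic, and its rank."""
    table = centralities.copy()
    ratio_cols = []
    for col in CENTRALITY_INDICES:
        rc = f"r_{col}"
        table[rc] = _rank_ratios(table[col])
        ratio_cols.append(rc)
    table["q_stat"] = [
        q_fuse(np.sort(row)) for row in table[ratio_cols].to_numpy()
    ]
    order = np.lexsort((table.index.to_numpy(), table["q_stat"].to_numpy()))
    q_rank = np.empty(len(table), dtype=int)
    q_rank[order] = np.arange(1, len(table) + 1)
    table["q_rank"] = q_rank
    return table


def select_critical(table: pd.DataFrame, top_fraction: float = 0.01) -> list[str]:
    """Genes in the top fraction by ascending Q (smallest = most central).

    Returns ceil(top_fraction * n_nodes) genes; ties at the cut break
    lexicographically (and are logged).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if "q_stat" not in table.columns:
        raise ValueError("table lacks q_stat; run add_q_statistic first")
    n_out = math.ceil(top_fraction * len(table))
    order = np.lexsort((table.index.to_numpy(), table["q_stat"].to_numpy()))
    ranked = table.index.to_numpy()[order]
    cut_q = table["q_stat"].to_numpy()[order][n_out - 1]
    n_tied = int((table["q_stat"] == cut_q).sum())
    if n_tied > 1:
        logger.info("%d node(s) tied at the Q cut; lexicographic tie-break", n_tied)
    return list(ranked[:n_out])


def rank_network(
    net: Network, top_fraction: float = 0.01, *, directed_all: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """End-to-end: centralities -> rank ratios -> Q -> critical-gene list."""
    table = add_q_statistic(compute_centralities(net, directed_all=directed_all))
    return table, select_critical(table, top_fraction)
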