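"""Co-consumption network construction and descriptive metrics.

An edge between two food groups asserts that participants who eat more of
one tend to eat more of the other. Edges are validated by split-half
resampling: the cohort is repeatedly split into a test and a validation
half, the Spearman correlation of every pair is computed in both halves,
and a pair is connected only if it is significant (and positive) in *both*
halves of *every* repeat and its mean test-half correlation clears a soft
threshold (default 0.2). The surviving mean correlation becomes the edge
weight; consumer counts from the binarized matrix become node weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeValidationConfig",
    "spearman_pairwise",
    "validate_edges",
    "build_graph",
    "centralities",
    "maximal_cliques",
    "module_density",
]

_MIN_PAIRWISE = 3  # minimum sample for a rank correlation
_MIN_SUBSET = 4  # minimum size of each resampling half


@dataclass(frozen=True)
class EdgeValidationConfig:
    """Resampling-validation settings for edge inference.

    ``n_repeats`` split-half repetitions; each repeat puts
    ``split_fraction`` of participants in the test half and the rest in the
    validation half. ``alpha`` is the per-test two-sided significance level,
    ``r_threshold`` the soft threshold the mean test-half correlation must
    exceed, and ``require_positive`` demands a positive coefficient in every
    half of every repeat.
    """

    n_repeats: int = 100
    split_fraction: float = 0.5
    alpha: float = 0.05
    r_threshold: float = 0.2
    require_positive: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.r_threshold < 0:
            raise ValueError("r_threshold must be >= 0")

    def with_seed(self, seed: int | None) -> "EdgeValidationConfig":
        return replace(self, seed=seed)


def _rank_matrix_correlation(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p for a (n, g) value matrix.

    Mid-ranks for ties; p from the t approximation t = r sqrt((n-2)/(1-r^2))
    (the convention of scipy.stats.spearmanr). Pairs involving a constant
    column get rho = p = NaN — they can never become edges.
    """
    n = values.shape[0]
    ranks = stats.rankdata(values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, p)
    # perfectly correlated pairs: t is +-inf -> sf gives 0, which is fine
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p


def spearman_pairwise(
    matrix: pd.DataFrame, subset: Sequence | pd.Index | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Spearman rho and p-value matrices over food-group columns.

    ``subset`` restricts to a participant index set (labels); at least four
    participants are required. Constant columns within the subset yield NaN
    for their pairs ("no correlation", never an edge).
    """
    sub = matrix if subset is None else matrix.loc[list(subset)]
    if sub.shape[0] < _MIN_PAIRWISE:
        raise ValueError(f"need at least {_MIN_PAIRWISE} participants, got {sub.shape[0]}")
    rho, p = _rank_matrix_correlation(sub.to_numpy(float))
    cols = matrix.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def validate_edges(matrix: pd.DataFrame, config: EdgeValidationConfig) -> pd.DataFrame:
    """Split-half resampling validation of all food-group pairs.

    Returns a DataFrame with columns ``source``, ``target``, ``rho`` (mean
    test-half correlation over all repeats) for every pair that was
    significant at ``config.alpha`` — and positive, if required — in both
    halves of every repeat and whose mean test correlation exceeds
    ``config.r_threshold``. Rows are sorted by (source, target).

    Rows are taken in sorted participant-ID order before splitting, so the
    result is invariant to the row order of ``matrix``.
    """
    ordered = matrix.sort_index(kind="stable")
    values = ordered.to_numpy(float)
    n, g = values.shape
    n_test = int(round(n * config.split_fraction))
    if min(n_test, n - n_test) < _MIN_SUBSET:
        raise ValueError(
            f"cohort of {n} too small for split_fraction={config.split_fraction}: "
            f"both halves need >= {_MIN_SUBSET} participants"
        )
    rng = np.random.default_rng(config.seed)
    alive = np.ones((g, g), dtype=bool)
    rho_sum = np.zeros((g, g))
    for _ in range(config.n_repeats):
        perm = rng.permutation(n)
        halves = (perm[:n_test], perm[n_test:])
        for which, idx in enumerate(halves):
            rho, p = _rank_matrix_correlation(values[idx])
            ok = np.isfinite(rho) & np.isfinite(p) & (p < config.alpha)
            if config.require_positive:
                ok &= rho > 0
            alive &= ok
            if which == 0:
                rho_sum += np.nan_to_num(rho)
    mean_rho = rho_sum / config.n_repeats
    keep = alive & (mean_rho > config.r_threshold)
    cols = ordered.columns
    rows = [
        (cols[i], cols[j], mean_rho[i, j])
        for i in range(g)
        for j in range(i + 1, g)
        if keep[i, j]
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "rho"])
    return edges.sort_values(["source", "target"], ignore_index=True)


def build_graph(edges: pd.DataFrame, scores: Mapping | pd.Series) -> nx.Graph:
    """Assemble the co-consumption graph.

    Every food group in ``scores`` becomes a node (isolates retained) with
    its consumption score as node attribute ``weight``; validated pairs
    become edges with the mean test correlation as edge ``weight``.
    """
    graph = nx.Graph()
    for node, score in dict(scores).items():
        graph.add_node(node, weight=int(score))
    for source, target, rho in edges[["source", "target", "rho"]].itertuples(index=False):
        if source not in graph or target not in graph:
            missing = source if source not in graph else target
            raise ValueError(f"edge endpoint {missing!r} has no consumption score")
        graph.add_edge(source, target, weight=float(rho))
    return graph


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per node.

    Computed on the unweighted topology: degree is the raw edge count;
    betweenness is shortest-path betweenness normalized to [0, 1] by
    (N−1)(N−2)/2; closeness is the Wasserman–Faust within-component
    closeness scaled by (reachable−1)/(N−1). Isolated nodes score 0 on all
    three.
    """
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    return pd.DataFrame(
        {
            "degree": dict(graph.degree()),
            "betweenness": betweenness,
            "closeness": closeness,
        }
    ).loc[list(graph.nodes)]


def maximal_cliques(graph: nx.Graph, min_size: int = 1) -> list[tuple]:
    """All maximal cliques with at least ``min_size`` nodes, sorted.

    Each clique is returned as a sorted tuple of node names; the list is
    sorted by (−size, members) so the largest cliques come first in a
    deterministic order.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: (-len(c), c))


def module_density(graph: nx.Graph, nodes: Iterable) -> float:
    """Connections per node: internal edge count divided by module size.

    This is the "density" used to compare modules (edges/node), not the
    conventional 2m/n(n−1) graph density.
    """
    node_set = set(nodes)
    if not node_set:
        raise ValueError("module_density of an empty node set is undefined")
    missing = node_set - set(graph.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)}")
    internal = graph.subgraph(node_set).number_of_edges()
    return internal / len(node_set)
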