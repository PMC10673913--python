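"""Stratum-differential co-consumption networks and the age-trend network.

A differential network contrasts two cohort strata (male vs female, or
normal liver CAP < 238 dB/m vs hepatic steatosis CAP ≥ 293 dB/m): each
stratum gets its own fully validated co-consumption network and the
differential edges are the symmetric difference, every edge tagged with the
single stratum it came from and weighted 1.

The age-trend network looks across three age strata (< 30, 30–50, > 50
years) and keeps a food-group pair when its per-stratum Spearman
correlation either increases strictly across the three strata or rises by
more than 0.25 from the youngest to the oldest stratum, provided the pair
is significantly positively correlated in the oldest stratum. Edges are
tagged within- vs between-module against a reference partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .data import binarize, consumption_score
from .network import EdgeValidationConfig, build_graph, spearman_pairwise, validate_edges

__all__ = [
    "stratify",
    "stratified_ccn",
    "differential_network",
    "AgeTrendConfig",
    "age_trend_network",
    "DISEASE_NORMAL_MAX_CAP",
    "DISEASE_NAFLD_MIN_CAP",
]

DISEASE_NORMAL_MAX_CAP = 238.0
DISEASE_NAFLD_MIN_CAP = 293.0

AGE_YOUNG_MAX = 30.0
AGE_OLD_MIN = 50.0

#: a stratum must leave at least this many participants in each split half
_MIN_STRATUM = 8


def stratify(
    covariates: pd.DataFrame,
    by: str,
    age_cutoffs: tuple[float, float] = (AGE_YOUNG_MAX, AGE_OLD_MIN),
    cap_cutoffs: tuple[float, float] = (DISEASE_NORMAL_MAX_CAP, DISEASE_NAFLD_MIN_CAP),
) -> dict[str, pd.Index]:
    """Partition (or for disease: sub-select) participants into strata.

    ``by`` is one of ``"sex"`` (male/female), ``"disease"`` (normal:
    CAP < 238; nafld: CAP ≥ 293; the 238–293 band belongs to neither
    stratum) or ``"age"`` (young: < 30; middle: 30–50 inclusive of both
    bounds; old: > 50 — every participant falls in exactly one stratum).
    """
    if by == "sex":
        sex = covariates["sex"]
        return {
            "male": covariates.index[sex == "male"],
            "female": covariates.index[sex == "female"],
        }
    if by == "disease":
        cap = covariates["cap"].astype(float)
        lo, hi = cap_cutoffs
        return {
            "normal": covariates.index[cap < lo],
            "nafld": covariates.index[cap >= hi],
        }
    if by == "age":
        age = covariates["age"].astype(float)
        young, old = age_cutoffs
        return {
            "young": covariates.index[age < young],
            "middle": covariates.index[(age >= young) & (age <= old)],
            "old": covariates.index[age > old],
        }
    raise ValueError(f"unknown stratification rule {by!r}")


def stratified_ccn(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    by: str,
    config: EdgeValidationConfig,
    **stratify_kwargs,
) -> dict[str, nx.Graph]:
    """Run the full network pipeline (binarize, validate, build) per stratum.

    Every stratum uses the identical validation configuration; a stratum too
    small to split is an error naming the stratum.
    """
    strata = stratify(covariates, by, **stratify_kwargs)
    graphs: dict[str, nx.Graph] = {}
    for name, idx in strata.items():
        if len(idx) < 2 * _MIN_STRATUM:
            raise ValueError(
                f"stratum {name!r} has {len(idx)} participants; "
                f"needs at least {2 * _MIN_STRATUM} for split-half validation"
            )
        sub = matrix.loc[idx]
        edges = validate_edges(sub, config)
        scores = consumption_score(binarize(sub))
        graphs[name] = build_graph(edges, scores)
    return graphs


def differential_network(
    graph_a: nx.Graph,
    graph_b: nx.Graph,
    tags: tuple[str, str] = ("a", "b"),
) -> nx.Graph:
    """Symmetric-difference network of two stratum CCNs.

    Keeps every node of the shared universe; each surviving edge appeared in
    exactly one stratum, carries that stratum's tag as attribute ``origin``
    and weight 1. Node attribute ``weight`` is the degree within the
    differential network itself.
    """
    if set(graph_a.nodes) != set(graph_b.nodes):
        raise ValueError("differential network requires identical node universes")
    edges_a = {frozenset(e) for e in graph_a.edges}
    edges_b = {frozenset(e) for e in graph_b.edges}
    diff = nx.Graph()
    diff.add_nodes_from(graph_a.nodes)
    for edge in edges_a - edges_b:
        u, v = sorted(edge)
        diff.add_edge(u, v, origin=tags[0], weight=1)
    for edge in edges_b - edges_a:
        u, v = sorted(edge)
        diff.add_edge(u, v, origin=tags[1], weight=1)
    nx.set_node_attributes(diff, dict(diff.degree()), "weight")
    return diff


@dataclass(frozen=True)
class AgeTrendConfig:
    """Settings of the age-trend network.

    ``delta``: minimum rise of the oldest- over the youngest-stratum
    correlation for the jump rule. ``alpha``: significance level for the
    positivity/eligibility test. ``eligibility`` picks the stratum in which
    the pair must be significantly positive (``"oldest"`` or ``"all"``);
    ``monotone`` picks the increase reading (``"strict"``: young < middle <
    old, or ``"pairwise"``: old > young only).
    """

    age_cutoffs: tuple[float, float] = (AGE_YOUNG_MAX, AGE_OLD_MIN)
    delta: float = 0.25
    alpha: float = 0.05
    eligibility: str = "oldest"
    monotone: str = "strict"

    def __post_init__(self) -> None:
        if self.eligibility not in ("oldest", "all"):
            raise ValueError("eligibility must be 'oldest' or 'all'")
        if self.monotone not in ("strict", "pairwise"):
            raise ValueError("monotone must be 'strict' or 'pairwise'")


def trend_keep(
    r_young: float, r_middle: float, r_old: float, config: AgeTrendConfig
) -> bool:
    """The increasing-correlation rule for one pair.

    Rule 1: the correlation increases with age (strict monotone across the
    three strata by default). Rule 2: the oldest-stratum correlation exceeds
    the youngest by more than ``delta``. Either rule keeps the pair.
    """
    if any(np.isnan(r) for r in (r_young, r_middle, r_old)):
        return False
    if config.monotone == "strict":
        rule1 = r_young < r_middle < r_old
    else:
        rule1 = r_old > r_young
    rule2 = (r_old - r_young) > config.delta
    return bool(rule1 or rule2)


def age_trend_network(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    partition: Mapping[Hashable, Hashable],
    config: AgeTrendConfig | None = None,
) -> nx.Graph:
    """Build the age-trend network over three age strata.

    Per-stratum correlations are full-stratum Spearman coefficients (the
    split-half machinery validates the base CCN, not these trend deltas).
    Kept edges carry ``trend_magnitude`` (oldest minus youngest correlation),
    ``module_relation`` (``"within"`` when both endpoints share a module of
    ``partition``, else ``"between"``) and weight 1.
    """
    config = config or AgeTrendConfig()
    strata = stratify(covariates, "age", age_cutoffs=config.age_cutoffs)
    for name, idx in strata.items():
        if len(idx) < _MIN_STRATUM:
            raise ValueError(f"age stratum {name!r} has only {len(idx)} participants")
    rho, pval = {}, {}
    for name, idx in strata.items():
        rho[name], pval[name] = spearman_pairwise(matrix, idx)

    graph = nx.Graph()
    graph.add_nodes_from(matrix.columns)
    cols = list(matrix.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1 :]:
            r_y = float(rho["young"].at[u, v])
            r_m = float(rho["middle"].at[u, v])
            r_o = float(rho["old"].at[u, v])
            if config.eligibility == "oldest":
                eligible = (r_o > 0) and (pval["old"].at[u, v] < config.alpha)
            else:
                eligible = all(
                    rho[s].at[u, v] > 0 and pval[s].at[u, v] < config.alpha
                    for s in strata
                )
            if not eligible or not trend_keep(r_y, r_m, r_o, config):
                continue
            same_module = (
                u in partition and v in partition and partition[u] == partition[v]
            )
            graph.add_edge(
                u,
                v,
                weight=1,
                trend_magnitude=r_o - r_y,
                module_relation="within" if same_module else "between",
            )
    nx.set_node_attributes(graph, dict(graph.degree()), "weight")
    return graph
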