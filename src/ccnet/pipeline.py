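"""End-to-end orchestration of the co-consumption analysis.

:func:`run_all` executes the full study pipeline on an intake matrix and a
covariate table: quartile binarization → split-half edge validation → graph
assembly → consensus label propagation → module naming → hypergeometric
membership → member comparison → sex- and disease-differential networks →
age-trend network → module-related clique tests. Every stochastic stage
draws its seed deterministically from the single run seed, so a run is
reproducible from its configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import cliques as cliques_mod
from . import community, differential, network
from .data import binarize, consumption_score

__all__ = ["RunConfig", "RunResult", "derive_seed", "run_all", "write_outputs"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """All fixed constants of the analysis in one serializable object."""

    n_repeats: int = 100
    split_fraction: float = 0.5
    alpha: float = 0.05
    r_threshold: float = 0.2
    require_positive: bool = True
    community_runs: int = 50
    membership_threshold: float = 0.1
    age_cutoffs: tuple[float, float] = (30.0, 50.0)
    cap_cutoffs: tuple[float, float, float] = (238.0, 260.0, 293.0)
    trend_delta: float = 0.25
    clique_min_size: int = 4
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.membership_threshold < 1:
            raise ValueError("membership_threshold must be in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.clique_min_size < 2:
            raise ValueError("clique_min_size must be >= 2")
        if not self.age_cutoffs[0] < self.age_cutoffs[1]:
            raise ValueError("age cutoffs must increase")
        if not self.cap_cutoffs[0] < self.cap_cutoffs[1] < self.cap_cutoffs[2]:
            raise ValueError("CAP cutoffs must increase")

    def edge_config(self, seed: int | None = None) -> network.EdgeValidationConfig:
        return network.EdgeValidationConfig(
            n_repeats=self.n_repeats,
            split_fraction=self.split_fraction,
            alpha=self.alpha,
            r_threshold=self.r_threshold,
            require_positive=self.require_positive,
            seed=derive_seed(self.seed, "edges") if seed is None else seed,
        )

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["age_cutoffs"] = list(self.age_cutoffs)
        payload["cap_cutoffs"] = list(self.cap_cutoffs)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("age_cutoffs", "cap_cutoffs"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class RunResult:
    """Everything the pipeline computed, ready for export."""

    config: RunConfig
    binarized: pd.DataFrame
    scores: pd.Series
    edges: pd.DataFrame
    graph: nx.Graph
    node_metrics: pd.DataFrame
    cliques: list[tuple]
    raw_partition: dict
    partition: dict
    modularity: float
    naming: dict
    membership: pd.DataFrame
    comparison: community.ComparisonResult
    diff_sex: nx.Graph
    diff_disease: nx.Graph
    trend: nx.Graph
    clique_tests: pd.DataFrame
    stage_seeds: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _two_largest_modules(partition: dict) -> dict:
    """Restrict a partition to its two largest modules (membership needs 2)."""
    sizes: dict = {}
    for node, mod in partition.items():
        sizes[mod] = sizes.get(mod, 0) + 1
    if len(sizes) <= 2:
        return dict(partition)
    keep = sorted(sizes, key=lambda m: (-sizes[m], str(m)))[:2]
    return {n: m for n, m in partition.items() if m in keep}


def run_all(
    intake: pd.DataFrame, covariates: pd.DataFrame, config: RunConfig | None = None
) -> RunResult:
    """Execute the full co-consumption analysis; see the module docstring."""
    config = config or RunConfig()
    seeds = {stage: derive_seed(config.seed, stage) for stage in ("edges", "communities")}

    with _stage("binarize"):
        binarized = binarize(intake)
        scores = consumption_score(binarized)
    with _stage("validate_edges"):
        edges = network.validate_edges(intake, config.edge_config(seeds["edges"]))
    with _stage("build_graph"):
        graph = network.build_graph(edges, scores)
        node_metrics = network.centralities(graph)
        all_cliques = network.maximal_cliques(graph, min_size=2)
    with _stage("communities"):
        raw_partition = community.consensus_partition(
            graph, n_runs=config.community_runs, seed=seeds["communities"]
        )
        q = community.modularity(graph, raw_partition)
    with _stage("membership"):
        member_partition = _two_largest_modules(raw_partition)
        membership = community.assign_membership(
            binarized, member_partition, config.membership_threshold
        )
        naming = community.name_modules_by_cap(membership, covariates, member_partition)
        membership = community.relabel_membership(membership, naming)
        named_partition = community.relabel_partition(member_partition, naming)
    with _stage("compare_members"):
        comparison = community.compare_members(
            membership, covariates, cap_cutoffs=config.cap_cutoffs
        )
    with _stage("differential_sex"):
        sex_graphs = differential.stratified_ccn(
            intake, covariates, "sex", config.edge_config(seeds["edges"])
        )
        diff_sex = differential.differential_network(
            sex_graphs["male"], sex_graphs["female"], tags=("male", "female")
        )
    with _stage("differential_disease"):
        disease_graphs = differential.stratified_ccn(
            intake,
            covariates,
            "disease",
            config.edge_config(seeds["edges"]),
            cap_cutoffs=(config.cap_cutoffs[0], config.cap_cutoffs[2]),
        )
        diff_disease = differential.differential_network(
            disease_graphs["normal"], disease_graphs["nafld"], tags=("normal", "nafld")
        )
    with _stage("age_trend"):
        trend = differential.age_trend_network(
            intake,
            covariates,
            named_partition,
            differential.AgeTrendConfig(
                age_cutoffs=config.age_cutoffs,
                delta=config.trend_delta,
                alpha=config.alpha,
            ),
        )
    with _stage("cliques"):
        clique_tests = cliques_mod.test_cliques(
            all_cliques,
            membership,
            binarized,
            named_partition,
            min_size=config.clique_min_size,
            fdr_alpha=config.fdr_alpha,
        )

    node_metrics = node_metrics.assign(
        module=[named_partition.get(n, "isolated" if graph.degree(n) == 0 else "unassigned")
                for n in node_metrics.index]
    )
    isolates = [n for n in graph.nodes if graph.degree(n) == 0]
    hub = max(graph.nodes, key=lambda n: graph.degree(n))
    module_nodes = {
        name: [n for n, m in named_partition.items() if m == name]
        for name in sorted(set(named_partition.values()))
    }
    label_counts = membership["label"].value_counts().to_dict()
    summary = {
        "n_participants": int(intake.shape[0]),
        "n_groups": int(intake.shape[1]),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_isolated": len(isolates),
        "isolated_nodes": sorted(isolates),
        "hub": str(hub),
        "hub_degree": int(graph.degree(hub)),
        "modularity": q,
        "n_modules": len(set(raw_partition.values())),
        "module_sizes": {k: len(v) for k, v in module_nodes.items()},
        "module_density": {
            k: network.module_density(graph, v) for k, v in module_nodes.items()
        },
        "membership_counts": {str(k): int(v) for k, v in sorted(label_counts.items())},
        "mean_cap": {
            "unhealthy": float(comparison.continuous.at["cap", "mean_unhealthy"]),
            "healthy": float(comparison.continuous.at["cap", "mean_healthy"]),
        },
        "cap_p_value": float(comparison.continuous.at["cap", "p"]),
        "diff_sex_edges": diff_sex.number_of_edges(),
        "diff_disease_edges": diff_disease.number_of_edges(),
        "trend_edges": trend.number_of_edges(),
        "trend_between_module_edges": sum(
            1 for _, _, d in trend.edges(data=True) if d["module_relation"] == "between"
        ),
        "cliques_tested": int(len(clique_tests)),
        "cliques_related": int(clique_tests["related"].sum()) if len(clique_tests) else 0,
    }

    return RunResult(
        config=config,
        binarized=binarized,
        scores=scores,
        edges=edges,
        graph=graph,
        node_metrics=node_metrics,
        cliques=all_cliques,
        raw_partition=raw_partition,
        partition=named_partition,
        modularity=q,
        naming=naming,
        membership=membership,
        comparison=comparison,
        diff_sex=diff_sex,
        diff_disease=diff_disease,
        trend=trend,
        clique_tests=clique_tests,
        stage_seeds=seeds,
        summary=summary,
    )


def _edge_table(graph: nx.Graph, attrs: tuple[str, ...]) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, **{a: d.get(a) for a in attrs}}
        for u, v, d in graph.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["source", "target", *attrs])
    return frame.sort_values(["source", "target"], ignore_index=True)


def write_outputs(result: RunResult, outdir: str | Path) -> Path:
    """Export every artifact of a run (CSV/GraphML/JSON) plus a log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    result.edges.to_csv(out / "edges.csv", index=False)
    result.node_metrics.assign(weight=result.scores).rename_axis("name").to_csv(
        out / "nodes.csv"
    )
    nx.write_graphml(result.graph, out / "network.graphml")
    result.membership.rename_axis("id").to_csv(out / "membership.csv")
    result.comparison.continuous.to_csv(out / "comparison_continuous.csv")
    result.comparison.categorical.to_csv(out / "comparison_categorical.csv", index=False)
    _edge_table(result.diff_sex, ("origin",)).to_csv(out / "differential_sex.csv", index=False)
    nx.write_graphml(result.diff_sex, out / "differential_sex.graphml")
    _edge_table(result.diff_disease, ("origin",)).to_csv(
        out / "differential_disease.csv", index=False
    )
    nx.write_graphml(result.diff_disease, out / "differential_disease.graphml")
    _edge_table(result.trend, ("trend_magnitude", "module_relation")).to_csv(
        out / "age_trend.csv", index=False
    )
    nx.write_graphml(result.trend, out / "age_trend.graphml")
    result.clique_tests.to_csv(out / "cliques.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    result.config.to_yaml(out / "config.yaml")
    with open(out / "run.log", "w") as fh:
        fh.write("ccnet run\n")
        fh.write(f"config: {dataclasses.asdict(result.config)}\n")
        for stage, seed in result.stage_seeds.items():
            fh.write(f"seed[{stage}] = {seed}\n")
        fh.write(f"module naming: {result.naming}\n")
    return out
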