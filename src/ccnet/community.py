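"""Community detection, participant membership and module-member comparison.

Food modules are found by asynchronous label propagation: every non-isolated
node starts with its own label, nodes are visited in random order and adopt
the most frequent label among their neighbors (ties broken uniformly at
random) until every node's label is modal in its neighborhood. Because the
algorithm is stochastic, a consensus over many seeded runs is taken and the
most frequent (canonicalized) partition wins; partition quality is scored by
Newman modularity Q = Σ_c (e_cc − a_c²).

Participants are assigned to modules by hypergeometric enrichment: among the
N food groups that carry a module label, a participant consuming n of them,
k inside module M (|M| = K), is a member of M when the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n), falls below a threshold (default
0.1). Members of both or neither module are labeled ``other``. Member groups
are then compared on age, energy, BMI and the CAP steatosis score (t-test)
and on sex and steatosis-grade distributions (chi-square).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "label_propagation",
    "canonical_form",
    "canonicalize",
    "consensus_partition",
    "modularity",
    "hypergeometric_membership",
    "assign_membership",
    "name_modules_by_cap",
    "relabel_partition",
    "relabel_membership",
    "cap_grade",
    "CAP_CUTOFFS",
    "STEATOSIS_GRADES",
    "ComparisonResult",
    "compare_members",
]

#: CAP cutoffs (dB/m) separating steatosis grades S0|S1|S2|S3
CAP_CUTOFFS = (238.0, 260.0, 293.0)
STEATOSIS_GRADES = ("S0", "S1", "S2", "S3")

OTHER_LABEL = "other"


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def canonical_form(partition: Mapping[Hashable, Hashable]) -> tuple[tuple, ...]:
    """Canonical representation of a node→module map.

    Modules become sorted member tuples, ordered by their smallest member;
    any relabeling of module ids maps to the same canonical form.
    """
    modules: dict[Hashable, list] = {}
    for node, mod in partition.items():
        modules.setdefault(mod, []).append(node)
    return tuple(sorted((tuple(sorted(m)) for m in modules.values()), key=lambda m: m[0]))


def canonicalize(partition: Mapping[Hashable, Hashable]) -> dict[Hashable, int]:
    """Relabel module ids as 0, 1, ... in canonical (smallest-member) order."""
    return {
        node: idx
        for idx, members in enumerate(canonical_form(partition))
        for node in members
    }


def label_propagation(
    graph: nx.Graph, seed: int | None = None, max_iter: int = 1000
) -> dict[Hashable, int]:
    """One asynchronous label-propagation run on the non-isolated nodes.

    Nodes are visited in a fresh random order each sweep and adopt the modal
    label of their neighborhood, breaking ties uniformly at random; a node
    whose current label is already among the modal labels keeps it. The run
    stops after a sweep with no change. Isolated nodes are excluded; an
    edgeless graph is an error (no communities are defined on it).
    """
    nodes = [n for n in graph.nodes if graph.degree(n) > 0]
    if not nodes:
        raise ValueError("label propagation needs a graph with at least one edge")
    rng = np.random.default_rng(seed)
    labels = {n: i for i, n in enumerate(nodes)}
    order = list(nodes)
    for _ in range(max_iter):
        rng.shuffle(order)
        changed = False
        for node in order:
            counts = Counter(labels[nb] for nb in graph[node])
            top = max(counts.values())
            modal = [lab for lab, c in counts.items() if c == top]
            if labels[node] in modal:
                continue
            labels[node] = modal[int(rng.integers(len(modal)))]
            changed = True
        if not changed:
            break
    else:  # pragma: no cover - convergence is guaranteed in practice
        raise RuntimeError(f"label propagation did not converge in {max_iter} sweeps")
    return canonicalize(labels)


def consensus_partition(
    graph: nx.Graph, n_runs: int = 50, seed: int | None = None
) -> dict[Hashable, int]:
    """Most frequent canonical partition over ``n_runs`` seeded LPA runs.

    Frequency ties are broken by higher modularity, then by lexicographic
    canonical form, making the consensus deterministic given the seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    tally: Counter[tuple] = Counter()
    for child in child_seeds:
        part = label_propagation(graph, seed=np.random.default_rng(child))
        tally[canonical_form(part)] += 1
    max_count = max(tally.values())
    top = [form for form, count in tally.items() if count == max_count]
    if len(top) > 1:
        def _q(form: tuple) -> float:
            return modularity(graph, {n: i for i, mod in enumerate(form) for n in mod})

        best_q = max(_q(form) for form in top)
        top = [form for form in top if _q(form) == best_q]
    best = min(top)  # lexicographic canonical form as the final tie-break
    return {node: idx for idx, members in enumerate(best) for node in members}


def modularity(graph: nx.Graph, partition: Mapping[Hashable, Hashable]) -> float:
    """Newman modularity Q = Σ_c (e_cc − a_c²) on the unweighted graph.

    ``e_cc`` is the fraction of edges with both endpoints in module c and
    ``a_c`` the fraction of edge endpoints attached to module-c nodes.
    Edges with an unlabeled endpoint count toward the total but to no
    module. Returns a value in [−1, 1]; a single all-in-one module gives 0.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity of an edgeless graph is undefined")
    internal: Counter = Counter()
    degree_sum: Counter = Counter()
    for u, v in graph.edges:
        cu, cv = partition.get(u), partition.get(v)
        if cu is not None and cu == cv:
            internal[cu] += 1
    for node, mod in partition.items():
        if node in graph:
            degree_sum[mod] += graph.degree(node)
    return float(
        sum(internal[c] / m - (degree_sum[c] / (2 * m)) ** 2 for c in degree_sum)
    )


# ---------------------------------------------------------------------------
# participant membership
# ---------------------------------------------------------------------------

def _module_sets(partition: Mapping[Hashable, Hashable]) -> dict[Hashable, set]:
    modules: dict[Hashable, set] = {}
    for node, mod in partition.items():
        modules.setdefault(mod, set()).add(node)
    return modules


def hypergeometric_membership(
    row: pd.Series,
    partition: Mapping[Hashable, Hashable],
    p_threshold: float = 0.1,
) -> tuple[Hashable, dict[Hashable, float]]:
    """Module membership of one participant from their binarized intake row.

    For each module M: N = labeled food groups, K = |M|, n = labeled groups
    the participant consumes, k = consumed groups inside M; the enrichment
    p-value is the upper tail P(X ≥ k) of Hypergeometric(N, K, n). The
    participant is a member of M iff p < ``p_threshold``; members of exactly
    one module get that module's id as label, members of both or neither get
    ``"other"``. A participant who consumes no labeled group has p = 1 for
    every module.
    """
    modules = _module_sets(partition)
    labeled = [g for g in row.index if g in partition]
    n_consumed = int(row[labeled].sum())
    pvals: dict[Hashable, float] = {}
    for mod, members in modules.items():
        k = int(row[sorted(members & set(labeled))].sum())
        pvals[mod] = float(stats.hypergeom.sf(k - 1, len(labeled), len(members), n_consumed))
    hits = [mod for mod, p in pvals.items() if p < p_threshold]
    label = hits[0] if len(hits) == 1 else OTHER_LABEL
    return label, pvals


def assign_membership(
    binarized: pd.DataFrame,
    partition: Mapping[Hashable, Hashable],
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Vectorized hypergeometric membership for every participant.

    Returns a DataFrame indexed by participant with one ``p_<module>``
    column per module and a ``label`` column holding the module id of
    participants enriched in exactly one module, else ``"other"``.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    modules = _module_sets(partition)
    labeled_cols = [g for g in binarized.columns if g in partition]
    if not labeled_cols:
        raise ValueError("no binarized column carries a module label")
    big_n = len(labeled_cols)
    consumed = binarized[labeled_cols].to_numpy()
    n_vec = consumed.sum(axis=1)
    result = pd.DataFrame(index=binarized.index)
    hit_count = np.zeros(len(binarized), dtype=int)
    single_hit = np.empty(len(binarized), dtype=object)
    for mod in sorted(modules, key=str):
        member_cols = [g for g in labeled_cols if g in modules[mod]]
        k_vec = binarized[member_cols].to_numpy().sum(axis=1)
        p = stats.hypergeom.sf(k_vec - 1, big_n, len(modules[mod]), n_vec)
        result[f"p_{mod}"] = p
        hit = p < p_threshold
        single_hit[hit & (hit_count == 0)] = mod
        hit_count += hit
    labels = np.where(hit_count == 1, single_hit, OTHER_LABEL)
    result["label"] = labels
    return result


def name_modules_by_cap(
    membership: pd.DataFrame,
    covariates: pd.DataFrame,
    partition: Mapping[Hashable, Hashable] | None = None,
) -> dict[Hashable, str]:
    """Name the two modules ``unhealthy``/``healthy`` by member mean CAP.

    The module whose enriched members carry the higher mean CAP score is the
    unhealthy one. If either module has no enriched members the larger
    module (by food-group count, requires ``partition``) is named unhealthy.
    """
    module_ids = sorted(
        {c.removeprefix("p_") for c in membership.columns if c.startswith("p_")}
    )
    ids = _match_module_ids(membership, module_ids)
    if len(ids) != 2:
        raise ValueError(f"module naming needs exactly two modules, got {len(ids)}")
    cap = covariates.loc[membership.index, "cap"]
    means = {}
    for mod in ids:
        members = membership["label"] == mod
        means[mod] = float(cap[members].mean()) if members.any() else np.nan
    if any(np.isnan(v) for v in means.values()):
        if partition is None:
            raise ValueError("a module has no members; pass partition for size fallback")
        sizes = {mod: len(mem) for mod, mem in _module_sets(partition).items()}
        unhealthy = max(ids, key=lambda m: (sizes.get(m, 0), str(m)))
    else:
        unhealthy = max(ids, key=lambda m: means[m])
    return {mod: ("unhealthy" if mod == unhealthy else "healthy") for mod in ids}


def _match_module_ids(membership: pd.DataFrame, string_ids: list[str]) -> list:
    # membership labels keep original module id types (ints); match the
    # stringified p_ column names back to the label values when possible
    observed = {str(v): v for v in membership["label"].unique() if v != OTHER_LABEL}
    return [observed.get(s, int(s) if s.isdigit() else s) for s in string_ids]


def relabel_partition(
    partition: Mapping[Hashable, Hashable], naming: Mapping[Hashable, str]
) -> dict[Hashable, str]:
    """Map module ids of a node→module partition through ``naming``."""
    return {node: naming[mod] for node, mod in partition.items()}


def relabel_membership(
    membership: pd.DataFrame, naming: Mapping[Hashable, str]
) -> pd.DataFrame:
    """Rename membership labels and p-value columns through ``naming``."""
    renamed = membership.rename(
        columns={f"p_{mod}": f"p_{name}" for mod, name in naming.items()}
    )
    renamed["label"] = membership["label"].map(lambda v: naming.get(v, v))
    return renamed


# ---------------------------------------------------------------------------
# steatosis grading and member comparison
# ---------------------------------------------------------------------------

def cap_grade(cap, cutoffs: tuple[float, float, float] = CAP_CUTOFFS):
    """Steatosis grade from the CAP score (dB/m).

    S0 below the first cutoff (normal liver), S1 and S2 on the left-closed
    middle intervals, S3 at and above the last cutoff (severe steatosis,
    the NAFLD stratum of the disease-differential network). Accepts a
    scalar or an array/Series; CAP must be positive.
    """
    arr = np.asarray(cap, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("CAP score must be positive")
    c1, c2, c3 = cutoffs
    grades = np.select(
        [arr < c1, arr < c2, arr < c3], STEATOSIS_GRADES[:3], default=STEATOSIS_GRADES[3]
    )
    if np.isscalar(cap):
        return str(grades[()])
    if isinstance(cap, pd.Series):
        return pd.Series(grades, index=cap.index, name="steatosis_grade")
    return grades


@dataclass
class ComparisonResult:
    """Member-comparison tables (the Table-2 shaped output).

    ``continuous``: per variable mean/SD in each member group with the
    two-sample t statistic and p-value. ``categorical``: per variable and
    level, counts and percentages with a per-variable chi-square p.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    continuous: pd.DataFrame
    categorical: pd.DataFrame


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0  # both groups constant at the same value
    return t, p


def compare_members(
    membership: pd.DataFrame,
    covariates: pd.DataFrame,
    group_a: str = "unhealthy",
    group_b: str = "healthy",
    equal_var: bool = True,
    cap_cutoffs: tuple[float, float, float] = CAP_CUTOFFS,
) -> ComparisonResult:
    """Compare the two member groups on covariates, excluding ``other``.

    Continuous variables (age, energy, BMI, CAP) are compared with the
    independent two-sample t-test (pooled variance by default; set
    ``equal_var=False`` for Welch). Sex and the steatosis-grade distribution
    are compared with the chi-square test (no continuity correction).
    """
    labels = membership["label"]
    idx_a = membership.index[labels == group_a]
    idx_b = membership.index[labels == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"need >= 2 participants per group, got {len(idx_a)} {group_a!r} "
            f"and {len(idx_b)} {group_b!r}"
        )
    cov_a, cov_b = covariates.loc[idx_a], covariates.loc[idx_b]

    cont_rows = []
    for var in ("age", "energy", "bmi", "cap"):
        a = cov_a[var].to_numpy(float)
        b = cov_b[var].to_numpy(float)
        t, p = _ttest(a, b, equal_var)
        cont_rows.append(
            {
                "variable": var,
                f"mean_{group_a}": a.mean(),
                f"sd_{group_a}": a.std(ddof=1),
                f"mean_{group_b}": b.mean(),
                f"sd_{group_b}": b.std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    continuous = pd.DataFrame(cont_rows).set_index("variable")

    cat_rows = []
    for var, series_a, series_b, levels in (
        ("sex", cov_a["sex"], cov_b["sex"], ["female", "male"]),
        (
            "steatosis_grade",
            cap_grade(cov_a["cap"], cap_cutoffs),
            cap_grade(cov_b["cap"], cap_cutoffs),
            list(STEATOSIS_GRADES),
        ),
    ):
        counts_a = series_a.value_counts().reindex(levels, fill_value=0)
        counts_b = series_b.value_counts().reindex(levels, fill_value=0)
        table = np.array([counts_a.to_numpy(), counts_b.to_numpy()])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] > 1:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            chi2, p = 0.0, 1.0
        for level in levels:
            cat_rows.append(
                {
                    "variable": var,
                    "level": level,
                    f"n_{group_a}": int(counts_a[level]),
                    f"pct_{group_a}": 100.0 * counts_a[level] / len(idx_a),
                    f"n_{group_b}": int(counts_b[level]),
                    f"pct_{group_b}": 100.0 * counts_b[level] / len(idx_b),
                    "chi2": float(chi2),
                    "p": float(p),
                }
            )
    categorical = pd.DataFrame(cat_rows)

    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        n_a=len(idx_a),
        n_b=len(idx_b),
        continuous=continuous,
        categorical=categorical,
    )
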