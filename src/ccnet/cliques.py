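"""Module-related cliques and their consumption association tests.

A clique of the co-consumption network is a set of food groups that are all
pairwise co-consumed. A participant is a *consumer of a clique* when their
binarized intake is 1 for every clique member. Cliques whose nodes all lie
in one module are tested for differential consumption between unhealthy-
and healthy-module members with a 2×2 chi-square test (consumes-all vs not
× member group), Benjamini–Hochberg corrected across the tested cliques; an
adjusted p below the FDR level marks the clique module-related.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["clique_consumers", "test_cliques"]


def clique_consumers(
    clique: Sequence[Hashable],
    binarized: pd.DataFrame,
    ids: Iterable | None = None,
) -> int:
    """Count participants (optionally restricted to ``ids``) consuming every
    food group of the clique."""
    members = list(clique)
    if not members:
        raise ValueError("clique must contain at least one food group")
    missing = [m for m in members if m not in binarized.columns]
    if missing:
        raise ValueError(f"clique nodes not in binarized matrix: {missing}")
    rows = binarized if ids is None else binarized.loc[list(ids)]
    return int(rows[members].all(axis=1).sum())


def test_cliques(
    cliques: Sequence[Sequence[Hashable]],
    membership: pd.DataFrame,
    binarized: pd.DataFrame,
    partition: Mapping[Hashable, str],
    min_size: int = 4,
    fdr_alpha: float = 0.05,
    group_a: str = "unhealthy",
    group_b: str = "healthy",
    yates: bool = False,
) -> pd.DataFrame:
    """Association of module-homogeneous cliques with module membership.

    Tests every clique of at least ``min_size`` nodes whose members all
    share one module label of ``partition`` (cliques spanning modules or
    touching unlabeled nodes are skipped). For each, consumers are counted
    among ``group_a`` and ``group_b`` members and compared by Pearson
    chi-square on the 2×2 table (no Yates correction unless requested);
    p-values are Benjamini–Hochberg adjusted across the tested cliques.

    Returns a frame with columns clique_size, members, module,
    count/pct per group, p, p_adjusted, related (adjusted p < ``fdr_alpha``)
    and low_expected (some expected cell count < 5), sorted by
    (−clique_size, members).
    """
    labels = membership["label"]
    idx_a = membership.index[labels == group_a]
    idx_b = membership.index[labels == group_b]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both member groups must be non-empty")

    rows = []
    for clique in cliques:
        members = tuple(sorted(clique))
        if len(members) < min_size:
            continue
        mods = {partition.get(m) for m in members}
        if len(mods) != 1 or None in mods:
            continue  # spans modules or touches an unlabeled node
        module = mods.pop()
        count_a = clique_consumers(members, binarized, idx_a)
        count_b = clique_consumers(members, binarized, idx_b)
        table = np.array(
            [
                [count_a, len(idx_a) - count_a],
                [count_b, len(idx_b) - count_b],
            ]
        )
        if (table.sum(axis=0) == 0).any():
            chi2, p, expected = 0.0, 1.0, table.astype(float)
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
        rows.append(
            {
                "clique_size": len(members),
                "members": "/".join(str(m) for m in members),
                "module": module,
                f"count_{group_a}": count_a,
                f"pct_{group_a}": 100.0 * count_a / len(idx_a),
                f"count_{group_b}": count_b,
                f"pct_{group_b}": 100.0 * count_b / len(idx_b),
                "chi2": float(chi2),
                "p": float(p),
                "low_expected": bool((expected < 5).any()),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "clique_size", "members", "module",
            f"count_{group_a}", f"pct_{group_a}",
            f"count_{group_b}", f"pct_{group_b}",
            "chi2", "p", "low_expected",
        ],
    )
    if len(result):
        _, adjusted, _, _ = multipletests(result["p"], method="fdr_bh")
        result["p_adjusted"] = adjusted
        result["related"] = result["p_adjusted"] < fdr_alpha
        result = result.sort_values(
            ["clique_size", "members"], ascending=[False, True], ignore_index=True
        )
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["related"] = pd.Series(dtype=bool)
    return result
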