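"""Intake matrices: I/O, item→group aggregation, quartile binarization, scores.

The central object is the *intake matrix*, a :class:`pandas.DataFrame` with
one row per participant (index = participant ID) and one column per food
group, holding daily intake in grams per day. Covariates live in a second
frame indexed the same way with columns ``age``, ``sex``, ``bmi``, ``energy``
and ``cap`` (the FibroScan controlled attenuation parameter, dB/m).

Binarization turns intake into consumer / non-consumer indicators: a
participant counts as a consumer of a food group when their intake is
strictly greater than the group's first quartile taken over the whole
cohort. The column sums of the binarized matrix are the *consumption
scores* used as node weights in the co-consumption network.
"""

from __future__ import annotations

from os import PathLike
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "load_intake",
    "save_intake",
    "validate_intake",
    "load_mapping",
    "aggregate_items",
    "binarize",
    "consumption_score",
    "load_covariates",
    "validate_covariates",
    "save_covariates",
]

_MAX_REPORTED_CELLS = 20

VALID_SEXES = ("male", "female")
COVARIATE_COLUMNS = ("age", "sex", "bmi", "energy", "cap")


class ValidationError(ValueError):
    """Raised when an input table violates the intake/covariate contracts."""


def _format_cells(cells: list[tuple[object, object]]) -> str:
    shown = ", ".join(f"({p!r}, {g!r})" for p, g in cells[:_MAX_REPORTED_CELLS])
    if len(cells) > _MAX_REPORTED_CELLS:
        shown += f", ... ({len(cells)} total)"
    return shown


def validate_intake(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an intake matrix and return it as float64.

    Checks: unique participant IDs and group names, no missing values,
    all values numeric and non-negative. Offending cells are named in the
    error message; nothing is imputed.
    """
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate participant IDs: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate food-group names: {dups}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric intake values: {exc}") from exc
    mask = values.isna()
    if mask.to_numpy().any():
        cells = [(p, g) for p, g in zip(*np.nonzero(mask.to_numpy()))]
        named = [(df.index[p], df.columns[g]) for p, g in cells]
        raise ValidationError(f"missing intake values at cells {_format_cells(named)}")
    neg = values.to_numpy() < 0
    if neg.any():
        named = [(df.index[p], df.columns[g]) for p, g in zip(*np.nonzero(neg))]
        raise ValidationError(f"negative intake values at cells {_format_cells(named)}")
    return values


def load_intake(path: str | PathLike, sep: str | None = None) -> pd.DataFrame:
    """Load and validate a wide intake matrix from CSV/TSV.

    The header row names the food groups; the first column holds participant
    IDs. ``sep=None`` sniffs the delimiter.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_intake(df)


def save_intake(df: pd.DataFrame, path: str | PathLike) -> None:
    """Write an intake (or binarized) matrix as CSV with an ``id`` column."""
    df.to_csv(path, index_label="id")


def load_mapping(path: str | PathLike) -> dict[str, str]:
    """Load an item→group mapping from two-column CSV or a YAML dict."""
    text_path = str(path)
    if text_path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, Mapping):
            raise ValidationError("YAML mapping file must contain a single mapping")
        return {str(k): str(v) for k, v in mapping.items()}
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValidationError("mapping CSV needs two columns: item, group")
    items = table.iloc[:, 0].astype(str)
    if items.duplicated().any():
        dups = items[items.duplicated()].unique().tolist()
        raise ValidationError(f"items mapped more than once: {dups}")
    return dict(zip(items, table.iloc[:, 1].astype(str)))


def aggregate_items(items: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Sum item columns into food-group columns.

    Every item column must appear in ``mapping``; group columns appear in
    order of first appearance among the item columns. Row totals (grams per
    participant) are conserved.
    """
    unmapped = [c for c in items.columns if c not in mapping]
    if unmapped:
        raise ValidationError(f"items without a group mapping: {unmapped}")
    renamed = items.rename(columns=dict(mapping))
    grouped = renamed.T.groupby(level=0, sort=False).sum().T
    return grouped


def binarize(df: pd.DataFrame, q: float = 0.25, interpolation: str = "linear") -> pd.DataFrame:
    """Binarize intake into consumer indicators by the per-group quartile rule.

    A participant is a consumer of a group (indicator 1) when their intake is
    *strictly greater* than the group's ``q`` quantile over all participants
    (default: the first quartile, linear interpolation between order
    statistics). For a tie-free column this marks 75% of participants; for a
    zero-inflated column with Q1 = 0 it marks exactly the non-zero intakes.
    Rank-based: invariant under any strictly increasing transform of a column.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    thresholds = df.quantile(q, interpolation=interpolation)
    return (df > thresholds).astype(np.int8)


def consumption_score(binarized: pd.DataFrame) -> pd.Series:
    """Per-group consumer counts (column sums of the binarized matrix).

    Used as the node weight of the co-consumption network.
    """
    return binarized.sum(axis=0).astype(int)


def validate_covariates(
    cov: pd.DataFrame, participants: pd.Index | None = None
) -> pd.DataFrame:
    """Validate a covariate table (age, sex, bmi, energy, cap).

    Sex is normalized to lowercase ``male``/``female``. If ``participants``
    is given, the row set must match it exactly.
    """
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing_cols:
        raise ValidationError(f"covariate table missing columns: {missing_cols}")
    cov = cov.copy()
    if cov.index.duplicated().any():
        raise ValidationError("duplicate participant IDs in covariate table")
    if cov[list(COVARIATE_COLUMNS)].isna().to_numpy().any():
        raise ValidationError("missing covariate values")
    cov["sex"] = cov["sex"].astype(str).str.lower()
    bad_sex = ~cov["sex"].isin(VALID_SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"sex must be male/female; offending IDs: {cov.index[bad_sex].tolist()[:10]}"
        )
    for col, floor in (("age", 0.0), ("cap", 0.0)):
        bad = cov[col].astype(float) <= floor
        if bad.any():
            raise ValidationError(
                f"{col} must be > {floor}; offending IDs: {cov.index[bad].tolist()[:10]}"
            )
    if participants is not None and set(cov.index) != set(participants):
        extra = sorted(set(map(str, cov.index)) - set(map(str, participants)))[:5]
        lacking = sorted(set(map(str, participants)) - set(map(str, cov.index)))[:5]
        raise ValidationError(
            f"covariate rows do not match intake participants (extra={extra}, missing={lacking})"
        )
    if participants is not None:
        cov = cov.loc[participants]
    return cov


def load_covariates(
    path: str | PathLike, participants: pd.Index | None = None
) -> pd.DataFrame:
    """Load a covariate CSV with columns id, age, sex, bmi, energy, cap."""
    cov = pd.read_csv(path, index_col=0)
    cov.index = cov.index.astype(str)
    return validate_covariates(cov, participants)


def save_covariates(cov: pd.DataFrame, path: str | PathLike) -> None:
    cov.to_csv(path, index_label="id")
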