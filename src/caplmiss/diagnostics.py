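"""Missing-data diagnostics: per-variable proportions and pattern tables.

Mirrors the standard descriptive toolkit for incomplete data: the
proportion of missing values per variable (a Table-1-style report) and
the table of unique missing/present patterns with their frequencies
(an aggregation-plot-style report), including the all-present pattern
whose count is the complete-case count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PatternTable:
    """Unique missingness patterns (1 = missing) with their counts."""

    variables: list[str]
    patterns: list[tuple[tuple[int, ...], int]]  # (pattern, count), sorted
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([p for p, _ in self.patterns], columns=self.variables)
        df["count"] = [c for _, c in self.patterns]
        return df

    @property
    def n_unique(self) -> int:
        return len(self.patterns)


def _check_variables(table: pd.DataFrame, variables: list[str]) -> None:
    unknown = [v for v in variables if v not in table.columns]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")


def missing_proportions(table: pd.DataFrame, variables: list[str] | None = None) -> pd.Series:
    """Proportion of missing values per variable (full precision).

    Use ``(missing_proportions(t) * 100).round(1)`` for a one-decimal
    percent report view.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    variables = list(table.columns) if variables is None else list(variables)
    _check_variables(table, variables)
    return table[variables].isna().mean()


def enumerate_patterns(table: pd.DataFrame, variables: list[str]) -> PatternTable:
    """All distinct missing/present vectors over the variables, with counts.

    Sorted by count descending, then lexicographically by pattern; the
    all-present pattern is included when it occurs.
    """
    if not variables:
        raise ValueError("need at least one variable")
    _check_variables(table, variables)
    ind = table[variables].isna().astype(int)
    counts: dict[tuple[int, ...], int] = {}
    for row in ind.itertuples(index=False, name=None):
        counts[row] = counts.get(row, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return PatternTable(variables=list(variables), patterns=ordered, n_total=len(table))


def complete_case_count(table: pd.DataFrame, variables: list[str] | None = None) -> int:
    """Number of rows with no missing cell among the variables.

    An empty variable list counts every row (vacuous completeness).
    """
    variables = list(table.columns) if variables is None else list(variables)
    _check_variables(table, variables)
    if not variables:
        return len(table)
    return int(table[variables].notna().all(axis=1).sum())


def proportions_report(table: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Report view: variable, n missing, percent missing to one decimal."""
    prop = missing_proportions(table, variables)
    n_missing = table[prop.index].isna().sum()
    return pd.DataFrame(
        {
            "variable": prop.index,
            "n_missing": n_missing.to_numpy(),
            "proportion_pct": np.round(prop.to_numpy() * 100, 1),
        }
    ).reset_index(drop=True)
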