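"""Group comparisons, effect sizes and the imputed-vs-original contrast.

Cohen's d uses the pooled-standard-deviation convention

    d = (mean1 - mean2) / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2))

with group 1 the reference (e.g. children *with* pedometer data) so
that a positive d means the reference group scores higher.

The imputation contrast stacks the original scored dataset with the m
re-scored imputed datasets, labels them 0..m (0 = original, the
reference) and regresses each domain score on the dataset dummies by
ordinary least squares; the dummy coefficient for imputed dataset j is
the mean shift of that dataset relative to the original, with a
t-based p-value.  Per-imputation Cohen's d versus the original is
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OlsResult:
    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    names: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "p": self.pvalues}, index=self.names
        )


def cohens_d(n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float) -> float:
    """Standardised mean difference with the pooled SD in the denominator."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return (mean1 - mean2) / pooled


def cohens_d_from_samples(x1: np.ndarray, x2: np.ndarray) -> float:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohens_d(len(x1), float(np.mean(x1)), float(np.std(x1, ddof=1)),
                    len(x2), float(np.mean(x2)), float(np.std(x2, ddof=1)))


def ols(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> OlsResult:
    """Ordinary least squares with classical t-based inference.

    ``X`` must include any intercept column; rank deficiency is
    rejected rather than silently resolved.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    names = names or [f"x{i}" for i in range(p)]
    return OlsResult(params=beta, se=se, pvalues=pvals, df_resid=df, names=list(names))


def group_summary(
    analysis_subset: pd.DataFrame,
    group: pd.Series,
    variables: list[str] | None = None,
    group_labels: tuple = (False, True),
) -> pd.DataFrame:
    """Per-variable n/mean/SD by a binary grouping, with Cohen's d.

    ``group_labels`` orders the groups; the first is the reference
    (group 1) in the d computation.  Rows where the variable itself is
    missing are excluded per group; if either group is empty for a
    variable, d is reported as NaN.
    """
    vals = pd.unique(group.dropna())
    if len(vals) < 2:
        raise ValueError("grouping variable is constant")
    if len(vals) > 2:
        raise ValueError("grouping variable must be binary")
    variables = variables or [c for c in analysis_subset.columns
                              if pd.api.types.is_numeric_dtype(analysis_subset[c])]
    rows = []
    for var in variables:
        rec: dict = {"variable": var}
        stats_by_group = {}
        for gi, glabel in enumerate(group_labels, start=1):
            x = analysis_subset.loc[group == glabel, var].dropna()
            rec[f"n{gi}"] = len(x)
            rec[f"mean{gi}"] = round(float(x.mean()), 2) if len(x) else np.nan
            rec[f"sd{gi}"] = round(float(x.std(ddof=1)), 2) if len(x) > 1 else np.nan
            stats_by_group[gi] = x
        x1, x2 = stats_by_group[1], stats_by_group[2]
        if len(x1) >= 2 and len(x2) >= 2:
            try:
                rec["d"] = round(cohens_d_from_samples(x1, x2), 2)
            except ValueError:
                rec["d"] = np.nan
        else:
            rec["d"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """Per-dataset mean shifts relative to the original, per score."""

    table: pd.DataFrame  # columns: score, dataset, beta, se, p, d
    n_used: dict[str, int]

    def betas(self, score: str) -> np.ndarray:
        t = self.table[self.table["score"] == score].sort_values("dataset")
        return t["beta"].to_numpy()


def imputation_contrast(
    original_scores: pd.DataFrame,
    imputed_score_tables: list[pd.DataFrame],
    scores: list[str] = ("pc", "db", "ku", "mc", "overall"),
) -> ContrastResult:
    """Regress each score on dataset dummies (original = reference).

    Stacks the original with the m imputed score tables, drops rows
    whose score is missing, and fits OLS with an intercept plus one
    dummy per imputed dataset.  Also reports each imputed dataset's
    Cohen's d against the original.
    """
    m = len(imputed_score_tables)
    if m == 0:
        raise ValueError("need at least one imputed dataset")
    for t in imputed_score_tables:
        missing = set(scores) - set(t.columns)
        if missing:
            raise KeyError(f"imputed table lacks scores: {sorted(missing)}")
    rows = []
    n_used: dict[str, int] = {}
    for score in scores:
        parts, labels = [], []
        for ds, tab in enumerate([original_scores] + list(imputed_score_tables)):
            vals = tab[score].astype(float).dropna().to_numpy()
            parts.append(vals)
            labels.append(np.full(len(vals), ds))
        yy = np.concatenate(parts)
        dd = np.concatenate(labels)
        n_used[score] = len(yy)
        X = np.column_stack([np.ones(len(yy))] + [(dd == j).astype(float)
                                                  for j in range(1, m + 1)])
        fit = ols(yy, X, names=["intercept"] + [f"dataset_{j}" for j in range(1, m + 1)])
        ref = parts[0]
        for j in range(1, m + 1):
            try:
                d = cohens_d_from_samples(parts[j], ref)
            except ValueError:
                d = np.nan
            rows.append({
                "score": score, "dataset": j, "beta": fit.params[j],
                "se": fit.se[j], "p": fit.pvalues[j], "d": d,
            })
    return ContrastResult(table=pd.DataFrame(rows), n_used=n_used)
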