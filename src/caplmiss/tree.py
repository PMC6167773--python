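"""Binary-classification recursive partitioning (CART) from scratch.

Used to model a missingness indicator (e.g. "pedometer steps missing")
on demographic predictors and to identify the strongest predictor of
missingness — a missing-at-random screen: if observed covariates such
as study site split the indicator well, the MAR assumption behind
chained-equation imputation is plausible.

Splits minimise the Gini impurity.  Numeric predictors are scanned
exhaustively over midpoints between distinct values.  Categorical
predictors are ordered by event rate and scanned over contiguous
prefixes, which is optimal for a binary outcome without searching all
2^k subsets.  Ties are broken deterministically by predictor column
order and then by the lowest threshold, so the tree is a pure function
of the data.  No pruning is performed; the intended use is descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-12


def gini(labels: np.ndarray) -> float:
    """Gini impurity 1 - p0^2 - p1^2 of a binary label vector."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty label vector")
    p1 = float(np.mean(y))
    return 1.0 - p1**2 - (1.0 - p1) ** 2


@dataclass(frozen=True)
class SplitRule:
    """x <= threshold (numeric) or x in categories (categorical) goes left."""

    variable: str
    threshold: float | None = None
    categories: frozenset | None = None

    def goes_left(self, x: np.ndarray) -> np.ndarray:
        if self.threshold is not None:
            return np.asarray(x, dtype=float) <= self.threshold
        return np.isin(np.asarray(x, dtype=object), list(self.categories))


@dataclass
class TreeNode:
    n: int
    impurity: float
    p_event: float
    depth: int
    rule: SplitRule | None = None
    decrease: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X), dtype=float)
        if self.is_leaf:
            out[:] = self.p_event
            return out
        go_left = self.rule.goes_left(X[self.rule.variable].to_numpy())
        out[go_left] = self.left.predict_proba(X.loc[go_left])
        out[~go_left] = self.right.predict_proba(X.loc[~go_left])
        return out

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "impurity": round(self.impurity, 6),
            "p_event": round(self.p_event, 6),
            "depth": self.depth,
        }
        if not self.is_leaf:
            d["variable"] = self.rule.variable
            if self.rule.threshold is not None:
                d["threshold"] = self.rule.threshold
            else:
                d["categories"] = sorted(map(str, self.rule.categories))
            d["decrease"] = self.decrease
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


def _numeric_scan(x: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[float | None, float]:
    """Best midpoint threshold by exhaustive scan; returns (threshold, decrease)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    cum1 = np.cumsum(ys)
    total1 = cum1[-1]
    parent = 1.0 - (total1 / n) ** 2 - (1 - total1 / n) ** 2
    # candidate cut after position i (left = xs[:i+1]); only where value changes
    idx = np.nonzero(np.diff(xs) > 0)[0]
    idx = idx[(idx + 1 >= min_leaf) & (n - idx - 1 >= min_leaf)]
    if idx.size == 0:
        return None, 0.0
    nl = (idx + 1).astype(float)
    nr = n - nl
    l1 = cum1[idx].astype(float)
    r1 = total1 - l1
    gl = 1.0 - (l1 / nl) ** 2 - (1 - l1 / nl) ** 2
    gr = 1.0 - (r1 / nr) ** 2 - (1 - r1 / nr) ** 2
    dec = parent - (nl / n) * gl - (nr / n) * gr
    best = int(np.argmax(dec))  # argmax takes the first (lowest threshold) on ties
    thr = float((xs[idx[best]] + xs[idx[best] + 1]) / 2.0)
    return thr, float(dec[best])


def _categorical_scan(x: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[frozenset | None, float]:
    """Best contiguous split after ordering categories by event rate."""
    ser = pd.Series(y, dtype=float)
    grp = ser.groupby(pd.Series(x, dtype=object)).agg(["mean", "count", "sum"])
    if len(grp) < 2:
        return None, 0.0
    # stable sort on event rate; prior index sort makes tie order deterministic
    grp = grp.sort_index(kind="stable").sort_values("mean", kind="stable")
    n = len(y)
    total1 = float(ser.sum())
    parent = 1.0 - (total1 / n) ** 2 - (1 - total1 / n) ** 2
    counts = grp["count"].to_numpy(dtype=float)
    sums = grp["sum"].to_numpy(dtype=float)
    nl = np.cumsum(counts)[:-1]
    l1 = np.cumsum(sums)[:-1]
    nr = n - nl
    r1 = total1 - l1
    ok = (nl >= min_leaf) & (nr >= min_leaf)
    if not ok.any():
        return None, 0.0
    gl = 1.0 - (l1 / nl) ** 2 - (1 - l1 / nl) ** 2
    gr = 1.0 - (r1 / nr) ** 2 - (1 - r1 / nr) ** 2
    dec = np.where(ok, parent - (nl / n) * gl - (nr / n) * gr, -np.inf)
    best = int(np.argmax(dec))
    cats = frozenset(grp.index[: best + 1])
    return cats, float(dec[best])


def best_split(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    kind: str = "numeric",
    min_leaf: int = 1,
    variable: str = "x",
) -> tuple[SplitRule | None, float]:
    """Best single split of a binary target on one predictor.

    Returns (rule, weighted impurity decrease); (None, 0.0) when no
    valid split exists (constant predictor, constant target, or the
    minimum-leaf constraint cannot be met).
    """
    x = np.asarray(pd.Series(x).to_numpy())
    y = np.asarray(pd.Series(y).to_numpy(), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    if np.all(y == y[0]):
        return None, 0.0
    if kind == "numeric":
        thr, dec = _numeric_scan(x.astype(float), y, min_leaf)
        if thr is None or dec <= _EPS:
            return None, 0.0
        return SplitRule(variable=variable, threshold=thr), dec
    if kind == "categorical":
        cats, dec = _categorical_scan(x, y, min_leaf)
        if cats is None or dec <= _EPS:
            return None, 0.0
        return SplitRule(variable=variable, categories=cats), dec
    raise ValueError(f"unknown predictor kind {kind!r}")


@dataclass
class TreeParams:
    """Stopping rules.

    ``cp`` is a complexity parameter in the rpart tradition: a split is
    kept only if its n-weighted impurity decrease is at least ``cp``
    times the root node's total impurity.  An absolute threshold alone
    admits chance splits on pure-noise data at realistic sample sizes,
    so the relative criterion is the operative one; ``min_decrease``
    remains as a numerical floor.
    """

    max_depth: int = 4
    min_leaf: int = 20
    min_decrease: float = 1e-4
    cp: float = 0.01


def _infer_kinds(X: pd.DataFrame) -> dict[str, str]:
    return {
        c: ("numeric" if pd.api.types.is_numeric_dtype(X[c]) else "categorical")
        for c in X.columns
    }


def _grow(X: pd.DataFrame, y: np.ndarray, params: TreeParams, kinds: dict[str, str],
          depth: int, root_cost: float) -> TreeNode:
    node = TreeNode(n=len(y), impurity=gini(y), p_event=float(np.mean(y)), depth=depth)
    if depth >= params.max_depth or len(y) < 2 * params.min_leaf or node.impurity == 0.0:
        return node
    best_rule, best_dec = None, 0.0
    for var in X.columns:  # column order breaks ties deterministically
        rule, dec = best_split(X[var], y, kinds[var], params.min_leaf, variable=var)
        if rule is not None and dec > best_dec + _EPS:
            best_rule, best_dec = rule, dec
    if (best_rule is None or best_dec < params.min_decrease
            or node.n * best_dec < params.cp * root_cost):
        return node
    go_left = best_rule.goes_left(X[best_rule.variable].to_numpy())
    node.rule = best_rule
    node.decrease = best_dec
    node.left = _grow(X.loc[go_left], y[go_left], params, kinds, depth + 1, root_cost)
    node.right = _grow(X.loc[~go_left], y[~go_left], params, kinds, depth + 1, root_cost)
    return node


def grow_tree(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    params: TreeParams | None = None,
) -> TreeNode:
    """Grow a CART tree of a binary indicator on a predictor table.

    Rows with a missing predictor are dropped (with a logged count);
    predictor types are inferred from dtypes (numeric vs categorical).
    """
    params = params or TreeParams()
    y = pd.Series(np.asarray(pd.Series(y).to_numpy(), dtype=float), index=X.index)
    keep = X.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d rows with missing predictors", n_drop)
        X, y = X.loc[keep], y.loc[keep]
    if len(y) == 0:
        raise ValueError("no complete rows to fit on")
    kinds = _infer_kinds(X)
    yv = y.to_numpy()
    root_cost = len(yv) * gini(yv) if len(yv) else 0.0
    return _grow(X, yv, params, kinds, depth=0, root_cost=root_cost)


def first_split_variable(tree: TreeNode) -> str | None:
    """Name of the root-split predictor (None for a single-leaf tree)."""
    return None if tree.is_leaf else tree.rule.variable


def importance(tree: TreeNode) -> dict[str, float]:
    """Total n-weighted impurity decrease accumulated per predictor."""
    acc: dict[str, float] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        acc[node.rule.variable] = acc.get(node.rule.variable, 0.0) + node.decrease * node.n
        walk(node.left)
        walk(node.right)

    walk(tree)
    return acc
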