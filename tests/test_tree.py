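"""Recursive partitioning: impurity, splits, determinism, oracles."""

import numpy as np
import pandas as pd
import pytest

from caplmiss import (
    MCAR,
    CohortParams,
    MissingnessMechanism,
    TreeParams,
    apply_missingness,
    best_split,
    first_split_variable,
    generate_cohort,
    gini,
    grow_tree,
    importance,
)
from caplmiss.missingness import default_mechanism
from caplmiss.pipeline import TREE_PREDICTORS


@pytest.mark.parametrize(
    "labels, expected",
    [([0, 0, 0], 0.0), ([0, 1, 0, 1], 0.5), ([1, 0, 0], 4 / 9)],
)
def test_gini_values(labels, expected):
    assert gini(np.array(labels)) == pytest.approx(expected)


def test_gini_empty_rejected():
    with pytest.raises(ValueError):
        gini(np.array([]))


def test_best_split_numeric_example():
    rule, dec = best_split([1, 2, 3, 4], [0, 0, 1, 1], "numeric")
    assert rule.threshold == pytest.approx(2.5)
    assert dec == pytest.approx(0.5)


def test_best_split_constant_target():
    rule, dec = best_split([1, 2, 3, 4], [1, 1, 1, 1], "numeric")
    assert rule is None and dec == 0.0


def test_best_split_constant_predictor():
    rule, dec = best_split([2, 2, 2, 2], [0, 1, 0, 1], "numeric")
    assert rule is None and dec == 0.0


def test_best_split_categorical_pure_category():
    x = np.array(["a", "a", "b", "b", "c", "c"], dtype=object)
    y = np.array([1, 1, 0, 0, 0, 0])
    rule, dec = best_split(x, y, "categorical")
    # the singleton event-holding category ends up alone on one side
    assert rule.categories in (frozenset({"a"}), frozenset({"b", "c"}))
    assert dec == pytest.approx(gini(y))


def test_numeric_scan_matches_exhaustive_enumeration(rng):
    """Vectorised scan equals a plain loop over every midpoint."""
    x = rng.normal(size=60)
    y = (x + rng.normal(0, 1, 60) > 0).astype(float)
    rule, dec = best_split(x, y, "numeric")
    parent = gini(y)
    best = (None, 0.0)
    for t in sorted(set((a + b) / 2 for a, b in zip(sorted(x)[:-1], sorted(x)[1:]))):
        left, right = y[x <= t], y[x > t]
        if len(left) == 0 or len(right) == 0:
            continue
        d = parent - len(left) / 60 * gini(left) - len(right) / 60 * gini(right)
        if d > best[1] + 1e-12:
            best = (t, d)
    assert dec == pytest.approx(best[1])
    assert rule.threshold == pytest.approx(best[0])


def _greedy_oracle(X, y, max_depth, min_leaf):
    """Loop-based greedy tree: same rules, independent implementation."""
    y = np.asarray(y, dtype=float)
    node = {"n": len(y), "p": float(y.mean())}
    if max_depth == 0 or len(y) < 2 * min_leaf or y.min() == y.max():
        return node
    best = None
    for var in X.columns:
        xv = X[var].to_numpy(dtype=float)
        for t in sorted(set((a + b) / 2 for a, b in zip(sorted(xv)[:-1], sorted(xv)[1:]))):
            sel = xv <= t
            if sel.sum() < min_leaf or (~sel).sum() < min_leaf:
                continue
            d = (gini(y) - sel.mean() * gini(y[sel]) - (~sel).mean() * gini(y[~sel]))
            if best is None or d > best[2] + 1e-12:
                best = (var, t, d)
    if best is None or best[2] < 1e-4:
        return node
    var, t, d = best
    sel = X[var].to_numpy(dtype=float) <= t
    node.update(var=var, thr=t,
                left=_greedy_oracle(X[sel], y[sel], max_depth - 1, min_leaf),
                right=_greedy_oracle(X[~sel], y[~sel], max_depth - 1, min_leaf))
    return node


def _compare(node, oracle):
    assert node.n == oracle["n"]
    assert node.p_event == pytest.approx(oracle["p"])
    if "var" in oracle:
        assert node.rule is not None
        assert node.rule.variable == oracle["var"]
        assert node.rule.threshold == pytest.approx(oracle["thr"])
        _compare(node.left, oracle["left"])
        _compare(node.right, oracle["right"])
    else:
        assert node.is_leaf


def test_depth2_tree_matches_bruteforce_oracle(rng):
    X = pd.DataFrame({"u": rng.normal(size=12), "v": rng.normal(size=12)})
    y = (X["u"] + 0.5 * X["v"] > 0).astype(float).to_numpy()
    tree = grow_tree(X, y, TreeParams(max_depth=2, min_leaf=2))
    _compare(tree, _greedy_oracle(X, y, 2, 2))


def test_root_split_matches_sklearn(rng):
    """Cross-check the root split against an established CART."""
    sklearn_tree = pytest.importorskip("sklearn.tree")
    X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
    y = ((X["b"] > 0.4) | (rng.random(300) < 0.05)).astype(int).to_numpy()
    mine = grow_tree(X, y, TreeParams(max_depth=1, min_leaf=5))
    clf = sklearn_tree.DecisionTreeClassifier(max_depth=1, min_samples_leaf=5, random_state=0)
    clf.fit(X.to_numpy(), y)
    assert mine.rule.variable == X.columns[clf.tree_.feature[0]]
    assert mine.rule.threshold == pytest.approx(clf.tree_.threshold[0], abs=1e-8)


def test_site_indicator_recovered_exactly():
    rng = np.random.default_rng(0)
    site = rng.choice(list("ABCD"), size=200)
    y = (site == "A").astype(float)
    X = pd.DataFrame({"noise": rng.normal(size=200), "site": site})
    tree = grow_tree(X, y, TreeParams(max_depth=3, min_leaf=5))
    assert first_split_variable(tree) == "site"
    assert np.abs(tree.predict_proba(X) - y).max() == 0.0


def test_row_permutation_invariance(masked_2k):
    masked, _ = masked_2k
    y = masked["steps_d1"].isna()
    X = masked[TREE_PREDICTORS]
    t1 = grow_tree(X, y)
    perm = masked.sample(frac=1.0, random_state=3)
    t2 = grow_tree(perm[TREE_PREDICTORS], perm["steps_d1"].isna())
    assert t1.to_dict() == t2.to_dict()


def test_training_error_never_increases_down_the_tree(masked_2k):
    masked, _ = masked_2k
    y = masked["steps_d1"].isna().to_numpy()
    X = masked[TREE_PREDICTORS].dropna()
    y = y[masked[TREE_PREDICTORS].notna().all(axis=1).to_numpy()]
    tree = grow_tree(X, y)

    def check(node):
        if node.is_leaf:
            return
        parent_err = min(node.p_event, 1 - node.p_event) * node.n
        child_err = sum(min(c.p_event, 1 - c.p_event) * c.n for c in (node.left, node.right))
        assert child_err <= parent_err + 1e-9
        check(node.left)
        check(node.right)

    check(tree)


def test_site_driven_missingness_selects_site(masked_2k):
    masked, _ = masked_2k
    tree = grow_tree(masked[TREE_PREDICTORS], masked["steps_d1"].isna())
    assert first_split_variable(tree) == "site"
    imp = importance(tree)
    assert max(imp, key=imp.get) == "site"


def test_tiny_sample_gives_single_leaf():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    tree = grow_tree(X, np.array([0, 1, 0]), TreeParams(min_leaf=20))
    assert tree.is_leaf


def test_mcar_missingness_finds_no_split():
    """Under pure MCAR there is no structure for the tree to find."""
    c = generate_cohort(CohortParams(n=3000), seed=77)
    mech = MissingnessMechanism().add("steps_d1", MCAR(0.3))
    masked, _ = apply_missingness(c, mech, seed=78)
    tree = grow_tree(masked[TREE_PREDICTORS], masked["steps_d1"].isna(), TreeParams())
    assert tree.is_leaf
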