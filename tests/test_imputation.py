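"""Chained-equation imputation: PMM, categorical models, MICE driver."""

import numpy as np
import pandas as pd
import pytest

from caplmiss import ImputationSpec, default_imputation_spec, mice, pmm_impute
from caplmiss import imputation as imp


def _linear_toy(rng, n=300, n_missing=60):
    x = rng.normal(0, 1, n)
    y = pd.Series(2.0 * x + rng.normal(0, 0.4, n))
    y.iloc[:n_missing] = np.nan
    return pd.DataFrame({"x": x}), y


# ------------------------------------------------------------------ PMM

def test_pmm_noop_when_complete(rng):
    X, y = _linear_toy(rng, n_missing=0)
    out = pmm_impute(y, X, rng=rng)
    pd.testing.assert_series_equal(out, y)


def test_pmm_support_property(rng):
    X, y = _linear_toy(rng)
    out = pmm_impute(y, X, k=5, rng=rng)
    observed = set(y.dropna())
    assert out.notna().all()
    assert all(v in observed for v in out.iloc[:60])


def test_pmm_deterministic_given_seed(rng):
    X, y = _linear_toy(rng)
    a = pmm_impute(y, X, rng=np.random.default_rng(5))
    b = pmm_impute(y, X, rng=np.random.default_rng(5))
    pd.testing.assert_series_equal(a, b)


def test_pmm_donors_come_from_nearest_predictions():
    """With a deterministic linear relation the k donors for a missing
    row are enumerable by brute-force ranking of |prediction - target|."""
    x = np.arange(10, dtype=float)
    y = pd.Series(3.0 * x)
    y.iloc[5] = np.nan  # missing at x=5
    out = pmm_impute(y, pd.DataFrame({"x": x}), k=3, rng=np.random.default_rng(0))
    # noiseless fit: predictions equal 3x; nearest observed to x=5 are x in {4, 6, 3 or 7}
    assert out.iloc[5] in {9.0, 12.0, 18.0, 21.0}


def test_pmm_degenerate_pool_uniform_over_observed(rng):
    X, y = _linear_toy(rng, n=60, n_missing=10)
    out = pmm_impute(y, X, k=50, rng=rng)  # k = all observed rows
    assert all(v in set(y.dropna()) for v in out.iloc[:10])


def test_pmm_needs_enough_observed_rows(rng):
    y = pd.Series([1.0, np.nan, np.nan, np.nan])
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError):
        pmm_impute(y, X, rng=rng)


def test_pmm_singular_design_falls_back_to_ridge(rng, caplog):
    X, y = _linear_toy(rng, n=100, n_missing=20)
    X["x2"] = X["x"] * 2.0  # exactly collinear
    with caplog.at_level("WARNING"):
        out = pmm_impute(y, X, rng=rng)
    assert out.notna().all()


# ---------------------------------------------------- categorical models

def test_balanced_binary_fill_frequency(rng):
    """With no signal, imputed categories are ~Bernoulli(1/2)."""
    y = pd.Series(rng.integers(0, 2, 2000).astype(float))
    y.iloc[:800] = np.nan
    out = imp.categorical_impute(y, pd.DataFrame({"z": rng.normal(0, 1, 2000)}),
                                 "polytomous", rng)
    assert out.iloc[:800].mean() == pytest.approx(0.5, abs=0.06)


def test_single_category_variable(rng):
    y = pd.Series([3.0, 3.0, 3.0, np.nan, np.nan])
    out = imp.categorical_impute(y, pd.DataFrame({"z": np.arange(5.0)}), "polytomous", rng)
    assert (out == 3.0).all()


def test_proportional_odds_matches_statsmodels(rng):
    """ML estimates agree with an independent cumulative-logit fitter."""
    sm_ord = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
    n = 800
    x = rng.normal(0, 1, n)
    latent = 1.2 * x + rng.logistic(0, 1, n)
    y = np.digitize(latent, [-1.0, 0.5, 1.5])
    fitter = imp.ProportionalOdds(x.reshape(-1, 1), y, 4)
    theta, info = fitter.fit()
    ref = sm_ord.OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=False)
    # statsmodels orders params as (beta, cutpoints...); ours as (cutpoints, beta)
    assert theta[-1] == pytest.approx(ref.params[0], abs=1e-4)
    assert theta[0] == pytest.approx(ref.params[1], abs=1e-4)


def test_proportional_odds_probabilities_monotone(rng):
    """Fitted category probabilities shift monotonically with the predictor."""
    n = 600
    x = rng.normal(0, 1, n)
    latent = 1.5 * x + rng.logistic(0, 1, n)
    y = np.digitize(latent, [-0.5, 0.8])
    fitter = imp.ProportionalOdds(x.reshape(-1, 1), y, 3)
    theta, _ = fitter.fit()
    grid = np.linspace(-2, 2, 9).reshape(-1, 1)
    P = fitter.probabilities(theta, grid)
    assert np.all(np.diff(P[:, 0]) <= 1e-9)   # lowest category falls with x
    assert np.all(np.diff(P[:, -1]) >= -1e-9)  # highest category rises with x
    assert np.allclose(P.sum(axis=1), 1.0)


def test_polytomous_matches_statsmodels(rng):
    smd = pytest.importorskip("statsmodels.discrete.discrete_model")
    n = 800
    x = rng.normal(0, 1, n)
    eta = np.column_stack([np.zeros(n), 0.8 * x - 0.2, -0.5 * x + 0.3])
    p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    y = np.array([rng.choice(3, p=pi) for pi in p])
    fitter = imp.PolytomousLogistic(x.reshape(-1, 1), y, 3)
    theta, _ = fitter.fit()
    ref = smd.MNLogit(y, np.column_stack([np.ones(n), x])).fit(disp=False)
    assert np.allclose(theta.reshape(2, 2), ref.params.T, atol=1e-5)


def test_categorical_fallback_on_separation(rng, caplog):
    """Perfect separation cannot converge; PMM-on-codes takes over."""
    x = np.concatenate([np.zeros(30), np.ones(30)])
    y = pd.Series(np.concatenate([np.zeros(30), np.ones(30)]))
    y.iloc[:5] = np.nan
    with caplog.at_level("WARNING", logger="caplmiss.imputation"):
        out = imp.categorical_impute(y, pd.DataFrame({"x": x}), "polytomous", rng)
    assert out.notna().all()
    assert set(out.unique()) <= {0.0, 1.0}


# ----------------------------------------------------------------- MICE

def test_initialize_fills_from_observed_support(rng):
    df = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan], "b": [1.0] * 4})
    spec = ImputationSpec(models={"a": "pmm"}, predictors={"a": ["b"]})
    out = imp.initialize(df, spec, rng)
    assert out["a"].notna().all()
    assert set(out["a"]) <= {1.0, 2.0}


def test_initialize_rejects_fully_missing(rng):
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    spec = ImputationSpec(models={"a": "pmm"}, predictors={"a": ["b"]})
    with pytest.raises(ValueError):
        imp.initialize(df, spec, rng)


def test_mice_no_missing_is_identity(rng):
    df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    spec = ImputationSpec(models={"a": "pmm"}, predictors={"a": ["b"]}, m=3, iterations=2)
    res = mice(df, spec)
    assert res.m == 3
    for t in res.tables:
        pd.testing.assert_frame_equal(t, df)


def test_mice_preserves_observed_cells(masked_2k):
    masked, _ = masked_2k
    cols = ["pacer_laps", "grip_kg", "sitreach_cm", "age", "site", "gender"]
    sub = masked[cols]
    spec = default_imputation_spec(sub, m=2, iterations=3, seed=4)
    res = mice(sub, spec)
    for t in res.tables:
        for c in cols:
            obs = sub[c].notna()
            assert (t.loc[obs, c] == sub.loc[obs, c]).all()
            assert t[c].notna().all()


def test_mice_pmm_values_within_observed_range(masked_2k):
    masked, _ = masked_2k
    cols = ["steps_d1", "steps_d2", "age", "site", "gender"]
    sub = masked[cols]
    res = mice(sub, default_imputation_spec(sub, m=1, iterations=3, seed=9))
    for c in ["steps_d1", "steps_d2"]:
        observed = set(sub[c].dropna())
        filled = res.tables[0].loc[sub[c].isna(), c]
        assert all(v in observed for v in filled)


def test_mice_deterministic_given_seed(rng):
    df = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
    df.loc[df.index[:40], "a"] = np.nan
    spec = ImputationSpec(models={"a": "pmm"}, predictors={"a": ["b"]}, m=2,
                          iterations=3, seed=7)
    r1 = mice(df, spec)
    r2 = mice(df, spec)
    for t1, t2 in zip(r1.tables, r2.tables):
        pd.testing.assert_frame_equal(t1, t2)


def _bivariate_mar(seed, n=2000, rho=0.8):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n)
    df = pd.DataFrame(z, columns=["a", "b"])
    p_miss = 0.6 / (1 + np.exp(-(1.5 * df["a"] - 0.3)))
    mask = rng.random(n) < p_miss
    dfm = df.copy()
    dfm.loc[mask, "b"] = np.nan
    return df, dfm


def test_mice_recovers_mar_mean_bivariate_normal():
    """Pooled post-imputation mean lands within 3 MC SEs of the truth
    while the complete-case mean is biased away from it."""
    df, dfm = _bivariate_mar(seed=31)
    truth = df["b"].mean()
    se = df["b"].std() / np.sqrt(len(df))
    spec = ImputationSpec(models={"b": "pmm"}, predictors={"b": ["a"]},
                          m=5, iterations=10, seed=13)
    res = mice(dfm, spec)
    pooled = np.mean([t["b"].mean() for t in res.tables])
    assert abs(pooled - truth) < 3 * se
    assert abs(dfm["b"].mean() - truth) > 3 * se


def test_mice_trace_is_stationary():
    """Imputed-value mean trace shows no trend on stationary data."""
    df, dfm = _bivariate_mar(seed=17)
    spec = ImputationSpec(models={"b": "pmm"}, predictors={"b": ["a"]},
                          m=2, iterations=30, seed=3)
    res = mice(dfm, spec)
    trace = res.trace_mean["b"]
    assert trace.shape == (2, 30)
    for chain in trace:
        tail = chain[-25:]
        slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
        assert abs(slope) < 0.02


def test_spec_validation():
    with pytest.raises(ValueError):
        ImputationSpec(models={"a": "pmm"}, m=0)
    with pytest.raises(ValueError):
        ImputationSpec(models={"a": "banana"})
    with pytest.raises(KeyError):
        mice(pd.DataFrame({"x": [1.0]}), ImputationSpec(models={"zz": "pmm"}))
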