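"""Multiple imputation by chained equations (MICE), from first principles.

Each incomplete variable is imputed from the others by a conditional
model matched to its type:

* continuous — predictive mean matching (PMM): a Bayesian linear
  regression is fitted on the observed rows (coefficients drawn from
  their approximate normal posterior, residual variance from a scaled
  inverse-chi-square draw); each missing row receives the *observed*
  value of a donor chosen uniformly among the k observed rows whose
  predicted mean is closest to the missing row's prediction.  Imputed
  values therefore always lie in the observed support.
* ordered categorical — proportional-odds (cumulative logit) model fit
  by Newton-Raphson maximum likelihood, coefficients drawn from the
  approximate posterior, categories sampled from the fitted
  probabilities.
* unordered categorical — polytomous (multinomial) logistic model,
  same fitting and draw scheme.

The chain starts from uniform draws out of each variable's observed
values and sweeps the variables in fixed left-to-right column order for
a configured number of iterations; m independent chains (seeded
``seed + chain``) yield m completed datasets.  Observed cells are never
altered.  Categorical fits that fail (separation, singular
information) fall back to PMM on integer category codes with a logged
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------- design

def build_design(X: pd.DataFrame, add_intercept: bool = True) -> np.ndarray:
    """Numeric design matrix: dummy-coded categoricals + intercept."""
    Z = pd.get_dummies(X, drop_first=True, dtype=float)
    M = Z.to_numpy(dtype=float)
    if add_intercept:
        M = np.column_stack([np.ones(len(M)), M])
    return M


# ------------------------------------------------------------------ PMM

def _bayes_linreg_draw(Zo: np.ndarray, yo: np.ndarray, rng: np.random.Generator):
    """(beta_hat, beta_star): point estimate and posterior draw."""
    n, p = Zo.shape
    A = Zo.T @ Zo
    b = Zo.T @ yo
    try:
        beta_hat = np.linalg.solve(A, b)
        V = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        logger.warning("singular design in PMM fit; using ridge fallback")
        A = A + 1e-6 * np.eye(p)
        beta_hat = np.linalg.solve(A, b)
        V = np.linalg.inv(A)
    resid = yo - Zo @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    try:
        L = np.linalg.cholesky((V + V.T) / 2.0)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky((V + V.T) / 2.0 + 1e-10 * np.eye(p))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return beta_hat, beta_star


def pmm_impute(
    y: pd.Series,
    X: pd.DataFrame,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Impute the missing entries of a continuous variable by PMM.

    Observed-row predictions use the point estimate, missing-row
    predictions use the posterior draw (type-1 matching); every fill is
    an observed donor value.
    """
    rng = rng or np.random.default_rng()
    obs = y.notna().to_numpy()
    if obs.all():
        return y.copy()
    Z = build_design(X)
    n, p = Z.shape
    if obs.sum() < p + 1:
        raise ValueError(f"need at least {p + 1} observed rows, have {int(obs.sum())}")
    yo = y.to_numpy(dtype=float)[obs]
    beta_hat, beta_star = _bayes_linreg_draw(Z[obs], yo, rng)
    pred_obs = Z[obs] @ beta_hat
    pred_mis = Z[~obs] @ beta_star

    k_eff = min(k, len(yo))
    fills = np.empty(len(pred_mis))
    # chunked donor search keeps the distance matrix small
    chunk = 512
    for start in range(0, len(pred_mis), chunk):
        pm = pred_mis[start:start + chunk]
        dist = np.abs(pred_obs[None, :] - pm[:, None])
        nearest = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
        pick = rng.integers(0, k_eff, size=len(pm))
        fills[start:start + chunk] = yo[nearest[np.arange(len(pm)), pick]]
    out = y.copy().astype(float)
    out.iloc[np.nonzero(~obs)[0]] = fills
    return out


# -------------------------------------------------- categorical models

def _num_hessian(grad_fn, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Forward-difference Jacobian of the gradient (observed information)."""
    d = len(theta)
    g0 = grad_fn(theta)
    H = np.empty((d, d))
    for j in range(d):
        t = theta.copy()
        t[j] += eps
        H[:, j] = (grad_fn(t) - g0) / eps
    return (H + H.T) / 2.0


def _newton(loglik_fn, grad_fn, theta0: np.ndarray, max_iter: int = 50,
            tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson ascent; returns (theta_hat, observed information)."""
    theta = theta0.copy()
    ll = loglik_fn(theta)
    if not np.isfinite(ll):
        raise ConvergenceError("non-finite initial log-likelihood")
    for _ in range(max_iter):
        g = grad_fn(theta)
        H = _num_hessian(grad_fn, theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError("singular information matrix") from e
        # H should be negative definite at an interior maximum
        new = theta - step
        ll_new = loglik_fn(new)
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-10) and halvings < 30:
            step = step / 2.0
            new = theta - step
            ll_new = loglik_fn(new)
            halvings += 1
        if halvings >= 30:
            raise ConvergenceError("step halving failed")
        converged = np.max(np.abs(new - theta)) < tol or abs(ll_new - ll) < tol
        theta, ll = new, ll_new
        if converged:
            info = -_num_hessian(grad_fn, theta)
            return theta, info
    raise ConvergenceError("Newton-Raphson did not converge")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class ProportionalOdds:
    """Cumulative-logit model P(y <= j | x) = sigmoid(alpha_j - x @ beta)."""

    def __init__(self, Z: np.ndarray, codes: np.ndarray, n_cat: int):
        self.Z = Z  # no intercept column; cutpoints play that role
        self.codes = codes
        self.K = n_cat
        self.p = Z.shape[1]

    def _unpack(self, theta):
        return theta[: self.K - 1], theta[self.K - 1:]

    def _cum(self, theta):
        alpha, beta = self._unpack(theta)
        eta = self.Z @ beta
        g = _sigmoid(alpha[None, :] - eta[:, None])  # n x (K-1)
        return np.hstack([np.zeros((len(eta), 1)), g, np.ones((len(eta), 1))])

    def loglik(self, theta) -> float:
        alpha = self._unpack(theta)[0]
        if np.any(np.diff(alpha) <= 0):
            return -np.inf
        G = self._cum(theta)
        i = np.arange(len(self.codes))
        p = G[i, self.codes + 1] - G[i, self.codes]
        if np.any(p <= 0):
            return -np.inf
        return float(np.sum(np.log(p)))

    def grad(self, theta) -> np.ndarray:
        G = self._cum(theta)
        i = np.arange(len(self.codes))
        upper = G[i, self.codes + 1]
        lower = G[i, self.codes]
        p = np.clip(upper - lower, 1e-12, None)
        du = upper * (1 - upper)  # d gamma / d (alpha_j - eta) at upper cut
        dl = lower * (1 - lower)
        ga = np.zeros(self.K - 1)
        for j in range(self.K - 1):
            ga[j] = np.sum(np.where(self.codes == j, du / p, 0.0)
                           - np.where(self.codes - 1 == j, dl / p, 0.0))
        gb = -self.Z.T @ ((du - dl) / p)
        return np.concatenate([ga, gb])

    def fit(self) -> tuple[np.ndarray, np.ndarray]:
        freqs = np.bincount(self.codes, minlength=self.K) / len(self.codes)
        cum = np.clip(np.cumsum(freqs)[:-1], 1e-4, 1 - 1e-4)
        alpha0 = np.log(cum / (1 - cum))
        for j in range(1, self.K - 1):  # strictly increasing start
            alpha0[j] = max(alpha0[j], alpha0[j - 1] + 1e-3)
        theta0 = np.concatenate([alpha0, np.zeros(self.p)])
        return _newton(self.loglik, self.grad, theta0)

    def probabilities(self, theta, Znew: np.ndarray) -> np.ndarray:
        alpha, beta = self._unpack(theta)
        eta = Znew @ beta
        g = _sigmoid(alpha[None, :] - eta[:, None])
        G = np.hstack([np.zeros((len(eta), 1)), g, np.ones((len(eta), 1))])
        return np.clip(np.diff(G, axis=1), 0.0, 1.0)


class PolytomousLogistic:
    """Multinomial logit with category 0 as reference."""

    def __init__(self, Z: np.ndarray, codes: np.ndarray, n_cat: int):
        self.Z = np.column_stack([np.ones(len(Z)), Z])
        self.codes = codes
        self.K = n_cat
        self.p = self.Z.shape[1]

    def _probs(self, theta, Z):
        B = theta.reshape(self.K - 1, self.p)
        eta = np.column_stack([np.zeros(len(Z)), Z @ B.T])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def loglik(self, theta) -> float:
        P = self._probs(theta, self.Z)
        p = P[np.arange(len(self.codes)), self.codes]
        if np.any(p <= 0):
            return -np.inf
        return float(np.sum(np.log(p)))

    def grad(self, theta) -> np.ndarray:
        P = self._probs(theta, self.Z)
        Y = np.zeros_like(P)
        Y[np.arange(len(self.codes)), self.codes] = 1.0
        G = self.Z.T @ (Y[:, 1:] - P[:, 1:])  # p x (K-1)
        return G.T.ravel()

    def fit(self) -> tuple[np.ndarray, np.ndarray]:
        theta0 = np.zeros((self.K - 1) * self.p)
        return _newton(self.loglik, self.grad, theta0)

    def probabilities(self, theta, Znew: np.ndarray) -> np.ndarray:
        return self._probs(theta, np.column_stack([np.ones(len(Znew)), Znew]))


def _posterior_draw(theta_hat: np.ndarray, info: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    try:
        V = np.linalg.inv((info + info.T) / 2.0)
        L = np.linalg.cholesky((V + V.T) / 2.0)
    except np.linalg.LinAlgError as e:
        raise ConvergenceError("non-positive-definite information") from e
    return theta_hat + L @ rng.standard_normal(len(theta_hat))


def categorical_impute(
    y: pd.Series,
    X: pd.DataFrame,
    model: str = "polytomous",
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Impute a categorical variable by its fitted conditional model.

    ``model`` is ``"proportional_odds"`` (ordered) or ``"polytomous"``
    (unordered).  On non-convergence the imputation falls back to PMM
    on integer category codes, clamped to the observed categories.
    """
    rng = rng or np.random.default_rng()
    obs = y.notna().to_numpy()
    if obs.all():
        return y.copy()
    observed_vals = y[obs]
    cats = sorted(pd.unique(observed_vals))
    if len(cats) == 1:
        out = y.copy()
        out.iloc[np.nonzero(~obs)[0]] = cats[0]
        return out
    code_map = {c: i for i, c in enumerate(cats)}
    codes = observed_vals.map(code_map).to_numpy(dtype=int)
    Z = build_design(X, add_intercept=False)
    # centre/scale columns for Newton stability
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    sd[sd == 0] = 1.0
    Zs = (Z - mu) / sd
    cls = ProportionalOdds if model == "proportional_odds" else PolytomousLogistic
    if model not in ("proportional_odds", "polytomous"):
        raise ValueError(f"unknown categorical model {model!r}")
    try:
        fitter = cls(Zs[obs], codes, len(cats))
        theta_hat, info = fitter.fit()
        theta_star = _posterior_draw(theta_hat, info, rng)
        P = fitter.probabilities(theta_star, Zs[~obs])
        if not np.all(np.isfinite(P)):
            raise ConvergenceError("non-finite fitted probabilities")
        u = rng.random(len(P))
        drawn = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
        drawn = np.clip(drawn, 0, len(cats) - 1)
    except ConvergenceError as e:
        logger.warning("categorical fit failed (%s); falling back to PMM on codes", e)
        y_codes = pd.Series(np.where(obs, y.map(code_map).to_numpy(dtype=float), np.nan),
                            index=y.index)
        filled = pmm_impute(y_codes, X, k=5, rng=rng)
        drawn = np.clip(np.round(filled.to_numpy()[~obs]), 0, len(cats) - 1).astype(int)
    out = y.copy()
    out.iloc[np.nonzero(~obs)[0]] = [cats[c] for c in drawn]
    return out


# ----------------------------------------------------------------- MICE

@dataclass
class ImputationSpec:
    """Configuration of one chained-equations run."""

    models: dict[str, str]                       # variable -> pmm|proportional_odds|polytomous
    predictors: dict[str, list[str]] = field(default_factory=dict)
    m: int = 5
    iterations: int = 50
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.iterations < 1 or self.k < 1:
            raise ValueError("m, iterations and k must all be >= 1")
        bad = {v: m for v, m in self.models.items()
               if m not in ("pmm", "proportional_odds", "polytomous")}
        if bad:
            raise ValueError(f"unknown models: {bad}")


@dataclass
class ImputedSet:
    """m completed tables plus per-chain convergence traces."""

    tables: list[pd.DataFrame]
    trace_mean: dict[str, np.ndarray]  # variable -> (m, iterations)
    trace_sd: dict[str, np.ndarray]
    spec: ImputationSpec
    seeds: list[int]

    @property
    def m(self) -> int:
        return len(self.tables)


ORDERED_DEFAULTS = ("mvpa_days", "grade")
UNORDERED_DEFAULTS = ("site", "gender")


def default_imputation_spec(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    m: int = 5,
    iterations: int = 50,
    k: int = 5,
    seed: int = 0,
) -> ImputationSpec:
    """Model assignment by variable type, mirroring standard practice.

    Counts and measurements are treated as continuous (PMM); day-count
    style variables (MVPA days, school grade) as ordered categorical;
    site and gender as unordered categorical.  Demographics (site, age,
    gender) are always included as predictors.
    """
    if variables is None:
        variables = [c for c in table.columns if table[c].isna().any()]
    variables = list(variables)
    # demographic predictors with missing cells must be imputed too
    for v in ("site", "age", "gender"):
        if v in table.columns and v not in variables and table[v].isna().any():
            variables.append(v)
    models = {}
    for v in variables:
        if v in ORDERED_DEFAULTS:
            models[v] = "proportional_odds"
        elif v in UNORDERED_DEFAULTS or not pd.api.types.is_numeric_dtype(table[v]):
            models[v] = "polytomous"
        else:
            models[v] = "pmm"
    always = [c for c in ("site", "age", "gender") if c in table.columns]
    predictors = {
        v: [p for p in dict.fromkeys(list(variables) + always) if p != v]
        for v in variables
    }
    return ImputationSpec(models=models, predictors=predictors, m=m,
                          iterations=iterations, k=k, seed=seed)


def initialize(table: pd.DataFrame, spec: ImputationSpec,
               rng: np.random.Generator) -> pd.DataFrame:
    """Fill every missing cell with a uniform draw from observed values."""
    work = table.copy()
    for var in spec.models:
        col = work[var]
        miss = col.isna()
        if not miss.any():
            continue
        observed = col.dropna().to_numpy()
        if len(observed) == 0:
            raise ValueError(f"variable {var!r} has no observed values")
        work.loc[miss, var] = rng.choice(observed, size=int(miss.sum()))
    return work


def _impute_one(var: str, model: str, y_masked: pd.Series, X: pd.DataFrame,
                k: int, rng: np.random.Generator) -> pd.Series:
    if model == "pmm":
        return pmm_impute(y_masked, X, k=k, rng=rng)
    return categorical_impute(y_masked, X, model=model, rng=rng)


def mice(table: pd.DataFrame, spec: ImputationSpec | None = None) -> ImputedSet:
    """Run m chained-equation chains and return the completed tables.

    Per chain: initialise, then sweep the spec variables in column
    order for the configured iterations, re-imputing each variable from
    the current values of its predictors.  Observed cells are passed
    through untouched.
    """
    spec = spec or default_imputation_spec(table)
    for var in spec.models:
        if var not in table.columns:
            raise KeyError(f"spec variable {var!r} not in table")
    visit = [c for c in table.columns if c in spec.models]  # left-to-right
    miss_masks = {v: table[v].isna() for v in visit}
    active = [v for v in visit if miss_masks[v].any()]

    tables: list[pd.DataFrame] = []
    seeds = [spec.seed + chain for chain in range(spec.m)]
    tm = {v: np.full((spec.m, spec.iterations), np.nan) for v in active}
    ts = {v: np.full((spec.m, spec.iterations), np.nan) for v in active}
    for chain, chain_seed in enumerate(seeds):
        rng = np.random.default_rng(chain_seed)
        work = initialize(table, spec, rng)
        for it in range(spec.iterations):
            for var in active:
                mask = miss_masks[var]
                y_masked = table[var]  # observed values + NaN at mask
                preds = [p for p in spec.predictors.get(var, []) if p in work.columns]
                X = work[preds]
                completed = _impute_one(var, spec.models[var], y_masked, X, spec.k, rng)
                work[var] = completed
                imputed_vals = pd.to_numeric(completed[mask], errors="coerce")
                tm[var][chain, it] = float(imputed_vals.mean())
                ts[var][chain, it] = float(imputed_vals.std(ddof=0))
        tables.append(work)
    return ImputedSet(tables=tables, trace_mean=tm, trace_sd=ts, spec=spec, seeds=seeds)
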