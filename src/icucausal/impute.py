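"""Multiple imputation by chained equations and Rubin's-rule pooling.

Fully conditional specification: each incomplete variable gets its own
conditional model given all other analysis variables (always including the
outcome), cycled until convergence.  Conditional models are predictive
mean matching with 5 donors for continuous variables, Bayesian logistic
draws for binary variables, and multinomial-logistic category draws for
unordered categoricals.  BMI is imputed directly and the obesity exposure
re-derived from it, preserving the deterministic exposure-BMI link.

Downstream per-imputation estimates are combined with Rubin's rules using
a t reference with the Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .cohort import CATEGORICAL_LEVELS, Cohort, DEFAULT_BMI_CUTOFF
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DEFAULT_M = 50
DEFAULT_N_ITER = 10
PMM_DONORS = 5

#: Analysis fields that may appear in imputation models (besides the target).
_CONTINUOUS_PREDICTORS = ["age", "income", "calendar_time", "bmi", "saps2"]
_BOOLEAN_PREDICTORS = ["hypothyroidism", "glucocorticoids", "dementia",
                       "hiv_aids", "hospital_death"]
_CATEGORICAL_PREDICTORS = ["sex", "ethnicity", "smoking", "alcohol",
                           "physical_activity", "solid_malignancy",
                           "heme_malignancy", "admission_type"]

#: Default set of variables to impute: the exposure-carrying BMI plus the
#: incomplete confounders.
DEFAULT_IMPUTE_VARIABLES = [
    "bmi", "ethnicity", "smoking", "alcohol", "physical_activity",
    "hypothyroidism", "glucocorticoids", "solid_malignancy",
    "heme_malignancy", "dementia", "hiv_aids",
]


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus imputation provenance."""

    completed: list[pd.DataFrame]
    variables: list[str]
    model_tags: dict[str, str]
    n_iterations: int
    seed: int | None
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF
    warnings: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.completed)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.completed):
            df.to_csv(path / f"imputed_{i:03d}.csv", index=False)
        manifest = dict(m=self.m, variables=self.variables,
                        model_tags=self.model_tags,
                        n_iterations=self.n_iterations, seed=self.seed,
                        bmi_cutoff=self.bmi_cutoff, warnings=self.warnings)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ImputationSet":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        completed = [pd.read_csv(p) for p in sorted(path.glob("imputed_*.csv"))]
        return cls(completed, manifest["variables"], manifest["model_tags"],
                   manifest["n_iterations"], manifest["seed"],
                   manifest["bmi_cutoff"], manifest["warnings"])


# ---------------------------------------------------------------------------
# Predictor encoding
# ---------------------------------------------------------------------------

def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design from all analysis fields except ``exclude``.

    Uses whatever values are currently filled in (observed or imputed).
    Rows must be complete at call time for the used fields.
    """
    cols: list[np.ndarray] = []
    for c in _CONTINUOUS_PREDICTORS:
        if c == exclude or c not in df.columns:
            continue
        x = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        sd = np.nanstd(x)
        cols.append((x - np.nanmean(x)) / (sd if sd > 0 else 1.0))
    for c in _BOOLEAN_PREDICTORS:
        if c == exclude or c not in df.columns:
            continue
        cols.append(df[c].fillna(False).to_numpy(dtype=float))
    for c in _CATEGORICAL_PREDICTORS:
        if c == exclude or c not in df.columns:
            continue
        levels = CATEGORICAL_LEVELS[c][1:]  # drop reference level
        for lev in levels:
            cols.append((df[c] == lev).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


# ---------------------------------------------------------------------------
# Conditional draws
# ---------------------------------------------------------------------------

def _draw_pmm(rng, X_obs, y_obs, X_mis, k: int = PMM_DONORS) -> np.ndarray:
    """Predictive mean matching (type-1) with a Bayesian coefficient draw."""
    n, p = X_obs.shape
    X1 = np.column_stack([np.ones(n), X_obs])
    XtX = X1.T @ X1 + 1e-8 * np.eye(p + 1)
    beta_hat = np.linalg.solve(XtX, X1.T @ y_obs)
    resid = y_obs - X1 @ beta_hat
    dof = max(n - p - 1, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    pred_obs = X1 @ beta_hat
    X1m = np.column_stack([np.ones(len(X_mis)), X_mis])
    pred_mis = X1m @ beta_star
    # k nearest observed predictions as the donor pool
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = np.empty(len(pred_mis))
    for i, (pm, po) in enumerate(zip(pred_mis, pos)):
        lo = max(0, po - k)
        hi = min(n, po + k)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist)[:k]]
        out[i] = y_obs[donors[rng.integers(0, len(donors))]]
    return out


def _draw_logistic(rng, X_obs, y_obs, X_mis) -> np.ndarray:
    """Bayesian logistic draw: sample coefficients, then Bernoulli."""
    X1 = np.column_stack([np.ones(len(X_obs)), X_obs])
    model = sm.GLM(y_obs.astype(float), X1, family=sm.families.Binomial())
    res = model.fit(maxiter=50)
    cov = np.asarray(res.cov_params())
    cov = (cov + cov.T) / 2 + 1e-10 * np.eye(len(cov))
    beta_star = rng.multivariate_normal(np.asarray(res.params), cov,
                                        method="eigh")
    X1m = np.column_stack([np.ones(len(X_mis)), X_mis])
    p = expit(X1m @ beta_star)
    return rng.random(len(X_mis)) < p


def _draw_multinomial(rng, X_obs, y_obs, X_mis, levels) -> np.ndarray:
    """Multinomial-logistic category draw from predicted probabilities."""
    clf = LogisticRegression(max_iter=200, C=1.0)
    clf.fit(X_obs, y_obs)
    proba = clf.predict_proba(X_mis)
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(clf.classes_, dtype=object)[idx]


def _marginal_draw(rng, observed: pd.Series, n: int):
    vals = observed.dropna().to_numpy()
    return vals[rng.integers(0, len(vals), size=n)]


# ---------------------------------------------------------------------------
# Chained imputation
# ---------------------------------------------------------------------------

def _variable_kind(var: str) -> str:
    if var in ("bmi", "age", "income", "calendar_time", "saps2"):
        return "pmm"
    if var in CATEGORICAL_LEVELS:
        return "multinomial"
    return "logistic"


def chained_impute(
    cohort: Cohort | pd.DataFrame,
    variables: Sequence[str] | None = None,
    m: int = DEFAULT_M,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
) -> ImputationSet:
    """Impute missing values by chained equations, ``m`` times.

    Each stream initializes missing cells by marginal draws from the
    observed values, then cycles ``n_iter`` times over the incomplete
    variables in descending-missingness order (ties alphabetical),
    refitting each variable's conditional model on currently-complete data
    and redrawing its missing cells.  Observed cells are never modified.
    A conditional model that fails to fit falls back to a marginal draw
    with a logged warning.
    """
    df0 = cohort.data if isinstance(cohort, Cohort) else cohort
    variables = list(DEFAULT_IMPUTE_VARIABLES) if variables is None else list(variables)
    unknown = [v for v in variables if v not in df0.columns]
    if unknown:
        raise ConfigError(f"unknown imputation variable(s): {unknown}")

    miss_frac = {v: float(df0[v].isna().mean()) for v in variables}
    impossible = [v for v in variables if miss_frac[v] >= 1.0]
    if impossible:
        raise DataError(f"variable(s) 100% missing, cannot impute: {impossible}")
    # visit order: descending missingness, ties alphabetical
    order = sorted((v for v in variables if miss_frac[v] > 0),
                   key=lambda v: (-miss_frac[v], v))
    masks = {v: df0[v].isna().to_numpy() for v in order}
    tags = {v: _variable_kind(v) for v in variables}
    warnings: list[str] = []

    streams = np.random.SeedSequence(seed).spawn(m)
    completed: list[pd.DataFrame] = []
    for s in streams:
        rng = np.random.default_rng(s)
        df = df0.copy()
        for v in order:
            df.loc[masks[v], v] = _marginal_draw(rng, df0[v], int(masks[v].sum()))
        for _ in range(n_iter if order else 0):
            for v in order:
                mask = masks[v]
                X_all = _encode_predictors(df, exclude=v)
                X_obs, X_mis = X_all[~mask], X_all[mask]
                kind = tags[v]
                try:
                    if kind == "pmm":
                        y_obs = pd.to_numeric(df0.loc[~mask, v]).to_numpy(dtype=float)
                        draw = _draw_pmm(rng, X_obs, y_obs, X_mis)
                    elif kind == "multinomial":
                        y_obs = df0.loc[~mask, v].to_numpy()
                        if len(pd.unique(y_obs)) < 2:
                            raise DataError("single observed category")
                        draw = _draw_multinomial(rng, X_obs, y_obs, X_mis,
                                                 CATEGORICAL_LEVELS[v])
                    else:
                        y_obs = df0.loc[~mask, v].astype("boolean").to_numpy(dtype=bool)
                        if y_obs.all() or (~y_obs).all():
                            raise DataError("degenerate binary variable")
                        draw = _draw_logistic(rng, X_obs, y_obs.astype(float), X_mis)
                except Exception as exc:
                    msg = f"conditional model for {v!r} failed ({exc}); marginal draw"
                    if msg not in warnings:
                        warnings.append(msg)
                        logger.warning(msg)
                    draw = _marginal_draw(rng, df0[v], int(mask.sum()))
                df.loc[mask, v] = draw
        if "bmi" in variables and "obesity" in df.columns:
            bmi = pd.to_numeric(df["bmi"], errors="coerce")
            df["obesity"] = pd.array(bmi >= bmi_cutoff, dtype="boolean")
        completed.append(df)
    return ImputationSet(completed, variables, tags, n_iter, seed,
                         bmi_cutoff, warnings)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m (estimate, variance) pairs."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    def as_effect(self, estimand="atu", method="tmle_sl",
                  data_treatment="imputed", n: int = 0):
        from .estimators import EffectEstimate
        return EffectEstimate(estimand, method, data_treatment, self.point,
                              self.se, self.ci_low, self.ci_high,
                              self.p_value, n,
                              {"m": self.m, "df": self.df})


def pool_rubin(
    estimates: Sequence[tuple[float, float]],
    df_complete: float | None = None,
) -> PooledEstimate:
    """Pool per-imputation (point, variance) pairs with Rubin's rules.

    Total variance T = W + (1 + 1/m) B, where W is the mean within-
    imputation variance and B the between-imputation variance of the
    points.  The CI and two-sided P use a t reference with Barnard-Rubin
    adjusted degrees of freedom when ``df_complete`` is given, otherwise
    the classical (m-1)/lambda^2 df (normal when B = 0).
    """
    if len(estimates) == 0:
        raise DataError("no estimates to pool")
    q = np.asarray([e[0] for e in estimates], dtype=float)
    v = np.asarray([e[1] for e in estimates], dtype=float)
    m = len(q)
    qbar = float(q.mean())
    W = float(v.mean())
    B = float(q.var(ddof=1)) if m > 1 else 0.0
    T = W + (1 + 1 / m) * B

    if B == 0 or m == 1 or T == 0:
        dof = np.inf
    else:
        lam = (1 + 1 / m) * B / T
        dof = (m - 1) / lam**2
        if df_complete is not None:
            nu_com = float(df_complete)
            nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            dof = dof * nu_obs / (dof + nu_obs)

    se = float(np.sqrt(T))
    tq = stats.t.ppf(0.975, dof) if np.isfinite(dof) else stats.norm.ppf(0.975)
    if se > 0:
        tstat = qbar / se
        p = float(2 * (stats.t.sf(abs(tstat), dof) if np.isfinite(dof)
                       else stats.norm.sf(abs(tstat))))
    else:
        p = 1.0 if qbar == 0 else 0.0
    return PooledEstimate(qbar, W, B, T, float(dof), se,
                          qbar - tq * se, qbar + tq * se, p, m)
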