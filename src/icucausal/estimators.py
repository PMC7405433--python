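"""Traditional-arm estimators and shared effect-measure machinery.

Implements the regression-based analysis: a main-effects logistic model
for in-hospital death (exposure + 14 confounders), odds-ratio reporting,
raw marginal risk differences with Wald intervals, two-proportion tests,
and G-computation (direct standardization) of the average effect of the
exposure in the unexposed (ATU) with delta-method or bootstrap standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import CONFOUNDERS, EXPOSURE, OUTCOME
from .design import full_design
from .errors import ConvergenceError, DataError

Z975 = 1.959964  # exact 97.5% normal quantile to 6 decimals


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class CoefficientRow:
    """One row of a logistic coefficient table on both scales."""

    term: str
    beta: float
    se: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(over="ignore"):
            self.or_ = float(np.exp(self.beta))
            self.ci_low = float(np.exp(self.beta - Z975 * self.se))
            self.ci_high = float(np.exp(self.beta + Z975 * self.se))
        z = self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)
        self.p_value = float(2 * stats.norm.sf(abs(z))) if self.se > 0 else 0.0


@dataclass
class EffectEstimate:
    """A risk-difference effect estimate (one cell of the summary grid)."""

    estimand: Literal["raw_rd", "atu", "att", "ate"]
    method: str
    data_treatment: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_point_se(cls, estimand, method, data_treatment, point, se, n=0, **extra):
        point, se = float(point), float(se)
        if se > 0:
            z = point / se
            p = float(2 * stats.norm.sf(abs(z)))
        else:
            p = 1.0 if point == 0 else 0.0
        return cls(estimand, method, data_treatment, point, se,
                   point - Z975 * se, point + Z975 * se, p, n, extra)


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficient table, covariance, design info."""

    table: list[CoefficientRow]
    params: pd.Series
    cov: pd.DataFrame
    standardization: dict[str, tuple[float, float]]
    confounders: list[str]
    n: int

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def coefficient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(term=r.term, beta=r.beta, se=r.se, odds_ratio=r.or_,
                  ci_low=r.ci_low, ci_high=r.ci_high, p_value=r.p_value)
             for r in self.table]
        )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(
    df: pd.DataFrame,
    outcome: str = OUTCOME,
    exposure: str | None = EXPOSURE,
    confounders: Sequence[str] | None = None,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> LogisticFit:
    """Fit the main-effects logistic outcome model on complete cases.

    Continuous confounders (age, income, calendar time) are z-standardized
    with constants computed on the analysis sample (or supplied), and the
    covariance is the observed-information (inverse Hessian) matrix.  All
    covariates stay in the model; no selection is performed.
    """
    confounders = CONFOUNDERS if confounders is None else list(confounders)
    X, consts = full_design(df, exposure=exposure,
                            standardization=standardization,
                            confounders=confounders)
    y = df[outcome].astype("boolean")
    if y.isna().any():
        raise DataError("outcome contains missing values")
    y = y.to_numpy(dtype=float)
    model = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # perfect separation and friends
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("IRLS did not converge in 100 iterations")
    score = model.score(res.params)
    if np.linalg.norm(score) > 1e-6 * max(1.0, len(y)):
        raise ConvergenceError(f"score norm too large: {np.linalg.norm(score):.3g}")
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    table = [CoefficientRow(t, float(params[t]), float(np.sqrt(cov.loc[t, t])))
             for t in X.columns]
    return LogisticFit(table, params, cov, consts, list(confounders), len(df))


def report_or(beta: float, se: float, term: str = "") -> CoefficientRow:
    """Odds-ratio row from a log-odds estimate and its standard error."""
    if se < 0:
        raise DataError("negative standard error")
    return CoefficientRow(term, float(beta), float(se))


# ---------------------------------------------------------------------------
# Raw risk differences and proportion tests
# ---------------------------------------------------------------------------

def raw_risk_difference(
    events_exposed: int, n_exposed: int,
    events_unexposed: int, n_unexposed: int,
    data_treatment: str = "complete_A",
) -> EffectEstimate:
    """Unadjusted risk difference (exposed minus unexposed) with Wald CI."""
    if n_exposed <= 0 or n_unexposed <= 0:
        raise DataError("group sizes must be positive")
    if events_exposed > n_exposed or events_unexposed > n_unexposed:
        raise DataError("event count exceeds group size")
    p1 = events_exposed / n_exposed
    p0 = events_unexposed / n_unexposed
    se = float(np.sqrt(p1 * (1 - p1) / n_exposed + p0 * (1 - p0) / n_unexposed))
    return EffectEstimate.from_point_se(
        "raw_rd", "regression", data_treatment, p1 - p0, se,
        n=n_exposed + n_unexposed,
        events_exposed=events_exposed, events_unexposed=events_unexposed)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided pooled-variance z-test for equality of two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise DataError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# G-computation
# ---------------------------------------------------------------------------

def _counterfactual_designs(fit: LogisticFit, df: pd.DataFrame):
    X, _ = full_design(df, standardization=fit.standardization,
                       confounders=fit.confounders)
    X1, X0 = X.copy(), X.copy()
    X1[EXPOSURE] = 1.0
    X0[EXPOSURE] = 0.0
    return X1.to_numpy(dtype=float), X0.to_numpy(dtype=float)


def gcomp_effect(
    fit: LogisticFit,
    df: pd.DataFrame,
    estimand: Literal["atu", "att", "ate"] = "atu",
    data_treatment: str = "complete_AC",
    se_method: Literal["delta", "bootstrap"] = "delta",
    n_boot: int = 500,
    seed: int | None = None,
) -> EffectEstimate:
    """Direct standardization (G-computation) of a marginal risk difference.

    Predicts each record's risk under exposure set to 1 and to 0, averages
    both over the estimand's reference subgroup (ATU: observed A = 0), and
    reports the difference.  The default SE is the delta method over the
    coefficient covariance (the standardization functional's gradient);
    ``se_method='bootstrap'`` refits on nonparametric resamples instead.
    """
    a = df[EXPOSURE].astype("boolean")
    if a.isna().any():
        raise DataError("exposure contains missing values in G-computation")
    a = a.to_numpy(dtype=bool)
    subgroup = {"atu": ~a, "att": a, "ate": np.ones(len(a), bool)}[estimand]
    if not subgroup.any():
        raise DataError(f"empty subgroup for estimand {estimand!r}")

    X1, X0 = _counterfactual_designs(fit, df)
    beta = fit.params.to_numpy(dtype=float)
    p1 = expit(X1 @ beta)
    p0 = expit(X0 @ beta)
    point = float(p1[subgroup].mean() - p0[subgroup].mean())

    if se_method == "delta":
        g1 = (p1 * (1 - p1))[subgroup, None] * X1[subgroup]
        g0 = (p0 * (1 - p0))[subgroup, None] * X0[subgroup]
        grad = (g1 - g0).mean(axis=0)
        var = float(grad @ fit.cov.to_numpy(dtype=float) @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    else:
        rng = np.random.default_rng(seed)
        n = len(df)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            bdf = df.iloc[idx].reset_index(drop=True)
            try:
                bfit = fit_logistic(bdf, confounders=fit.confounders)
            except ConvergenceError:
                continue
            ba = bdf[EXPOSURE].astype("boolean").to_numpy(dtype=bool)
            bsub = {"atu": ~ba, "att": ba, "ate": np.ones(n, bool)}[estimand]
            if not bsub.any():
                continue
            bX1, bX0 = _counterfactual_designs(bfit, bdf)
            bb = bfit.params.to_numpy(dtype=float)
            reps.append(float(expit(bX1 @ bb)[bsub].mean()
                              - expit(bX0 @ bb)[bsub].mean()))
        if len(reps) < 2:
            raise DataError("bootstrap produced fewer than 2 valid replicates")
        se = float(np.std(reps, ddof=1))

    return EffectEstimate.from_point_se(
        estimand, "regression_gcomp", data_treatment, point, se, n=len(df),
        se_method=se_method)


# ---------------------------------------------------------------------------
# Convenience: raw RD directly from a cohort frame
# ---------------------------------------------------------------------------

def raw_rd_from_cohort(df: pd.DataFrame,
                       data_treatment: str = "complete_A") -> EffectEstimate:
    """Raw risk difference among records with observed exposure."""
    a = df[EXPOSURE].astype("boolean")
    known = a.notna().to_numpy()
    av = a.fillna(False).to_numpy(dtype=bool)
    y = df[OUTCOME].astype("boolean").fillna(False).to_numpy(dtype=bool)
    exp_mask = known & av
    unexp_mask = known & ~av
    return raw_risk_difference(
        int(y[exp_mask].sum()), int(exp_mask.sum()),
        int(y[unexp_mask].sum()), int(unexp_mask.sum()),
        data_treatment=data_treatment)
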