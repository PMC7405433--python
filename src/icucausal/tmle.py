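"""One-step targeted maximum likelihood estimation of the ATU.

The estimand is the average effect of the exposure in the unexposed,
psi = E[Y(1) - Y(0) | A = 0]: the marginal causal risk difference in the
subpopulation that was not exposed.  Starting from initial outcome-risk
fits Q(0,W), Q(1,W) and a propensity fit g(W) (typically super learners),
a single logistic fluctuation with two clever covariates

    H1(A,W) = A (1 - g(W)) / (g(W) pi0),   H0(A,W) = -(1 - A) / pi0,

(pi0 = empirical P(A=0)) is fitted by maximum likelihood with logit Q as
offset and no intercept.  The updated surfaces Q* give the plug-in
psi_hat = mean over A=0 of [Q*(1,W) - Q*(0,W)], and the fluctuation's
score equations make the efficient-influence-function estimating equation
hold exactly: mean(D) = 0 with

    D = (H1 + H0) (Y - Q*(A,W)) + (1-A)/pi0 (Q*(1,W) - Q*(0,W) - psi).

The standard error is sd(D)/sqrt(n) (the influence curve), and extreme
propensities are truncated to fixed bounds [0.025, 0.975] by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .cohort import EXPOSURE, OUTCOME
from .design import confounder_design
from .errors import ConfigError, ConvergenceError, DataError
from .estimators import EffectEstimate, Z975
from .impute import ImputationSet, PooledEstimate, pool_rubin
from .learners import CandidateSpec, reduced_library
from .superlearner import SuperLearnerFit, fit_super_learner, sl_predict

DEFAULT_G_BOUNDS = (0.025, 0.975)
_QCLIP = 1e-6


# ---------------------------------------------------------------------------
# Propensity truncation
# ---------------------------------------------------------------------------

def truncate_propensity(
    g: np.ndarray,
    g_lo: float = DEFAULT_G_BOUNDS[0],
    g_hi: float = DEFAULT_G_BOUNDS[1],
) -> tuple[np.ndarray, float]:
    """Clip propensities to fixed bounds; report the fraction clipped.

    Bounds are absolute probabilities (the standard convention), not
    empirical percentiles of the weight distribution.
    """
    if not (0 < g_lo < g_hi < 1):
        raise ConfigError(f"invalid truncation bounds ({g_lo}, {g_hi})")
    g = np.asarray(g, dtype=float)
    clipped = np.clip(g, g_lo, g_hi)
    return clipped, float(np.mean(clipped != g))


# ---------------------------------------------------------------------------
# Targeting
# ---------------------------------------------------------------------------

@dataclass
class TargetedEstimate:
    """TMLE result: point, fluctuation, influence values, Wald inference."""

    psi: float
    epsilon: tuple[float, float]
    influence: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    q1_star: np.ndarray
    q0_star: np.ndarray
    fraction_truncated: float = 0.0
    n: int = 0

    def as_effect(self, data_treatment="complete_AC") -> EffectEstimate:
        return EffectEstimate("atu", "tmle_sl", data_treatment, self.psi,
                              self.se, self.ci_low, self.ci_high,
                              self.p_value, self.n,
                              {"epsilon": self.epsilon,
                               "fraction_truncated": self.fraction_truncated})


def _fit_fluctuation(y, offset, H):
    model = sm.GLM(y, H, family=sm.families.Binomial(), offset=offset)
    try:
        res = model.fit(maxiter=200, tol=1e-12)
    except Exception as exc:
        raise ConvergenceError(f"fluctuation fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("fluctuation fit did not converge")
    return np.asarray(res.params, dtype=float)


def tmle_atu(
    A: np.ndarray,
    Y: np.ndarray,
    Q0: np.ndarray,
    Q1: np.ndarray,
    g: np.ndarray,
    g_bounds: tuple[float, float] | None = DEFAULT_G_BOUNDS,
) -> TargetedEstimate:
    """One-step TMLE of E[Y(1) - Y(0) | A = 0] from nuisance predictions."""
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(A)
    pi0 = float((1 - A).mean())
    if pi0 == 0:
        raise DataError("no unexposed records; ATU undefined")

    if g_bounds is not None:
        g, frac_trunc = truncate_propensity(g, *g_bounds)
    else:
        g, frac_trunc = np.asarray(g, dtype=float), 0.0
    Q0 = np.clip(np.asarray(Q0, dtype=float), _QCLIP, 1 - _QCLIP)
    Q1 = np.clip(np.asarray(Q1, dtype=float), _QCLIP, 1 - _QCLIP)

    h1 = (1 - g) / (g * pi0)          # value of H1 on the exposed arm
    h0 = -1.0 / pi0                   # value of H0 on the unexposed arm
    H = np.column_stack([A * h1, (1 - A) * h0])
    offset = np.where(A == 1, logit(Q1), logit(Q0))
    eps = _fit_fluctuation(Y, offset, H)

    q1_star = expit(logit(Q1) + eps[0] * h1)
    q0_star = expit(logit(Q0) + eps[1] * h0)
    untreated = A == 0
    psi = float((q1_star - q0_star)[untreated].mean())

    q_star_obs = np.where(A == 1, q1_star, q0_star)
    D = (A * h1 + (1 - A) * h0) * (Y - q_star_obs) \
        + (1 - A) / pi0 * (q1_star - q0_star - psi)
    se = float(D.std(ddof=1) / np.sqrt(n))
    from scipy import stats
    p = float(2 * stats.norm.sf(abs(psi / se))) if se > 0 else 1.0
    return TargetedEstimate(psi, (float(eps[0]), float(eps[1])), D, se,
                            psi - Z975 * se, psi + Z975 * se, p,
                            q1_star, q0_star, frac_trunc, n)


def tmle_att(
    A: np.ndarray,
    Y: np.ndarray,
    Q0: np.ndarray,
    Q1: np.ndarray,
    g: np.ndarray,
    g_bounds: tuple[float, float] | None = DEFAULT_G_BOUNDS,
) -> TargetedEstimate:
    """One-step TMLE of the effect in the exposed, E[Y(1) - Y(0) | A = 1].

    Provided both in its own right and as the label-swap cross-check for
    :func:`tmle_atu` (ATU(A) = -ATT(1-A) with outcome surfaces and
    propensity recoded accordingly).
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(A)
    pi1 = float(A.mean())
    if pi1 == 0:
        raise DataError("no exposed records; ATT undefined")

    if g_bounds is not None:
        g, frac_trunc = truncate_propensity(g, *g_bounds)
    else:
        g, frac_trunc = np.asarray(g, dtype=float), 0.0
    Q0 = np.clip(np.asarray(Q0, dtype=float), _QCLIP, 1 - _QCLIP)
    Q1 = np.clip(np.asarray(Q1, dtype=float), _QCLIP, 1 - _QCLIP)

    h1 = 1.0 / pi1
    h0 = -g / ((1 - g) * pi1)
    H = np.column_stack([A * h1, (1 - A) * h0])
    offset = np.where(A == 1, logit(Q1), logit(Q0))
    eps = _fit_fluctuation(Y, offset, H)

    q1_star = expit(logit(Q1) + eps[0] * h1)
    q0_star = expit(logit(Q0) + eps[1] * h0)
    treated = A == 1
    psi = float((q1_star - q0_star)[treated].mean())

    q_star_obs = np.where(A == 1, q1_star, q0_star)
    D = (A * h1 + (1 - A) * h0) * (Y - q_star_obs) \
        + A / pi1 * (q1_star - q0_star - psi)
    se = float(D.std(ddof=1) / np.sqrt(n))
    from scipy import stats
    p = float(2 * stats.norm.sf(abs(psi / se))) if se > 0 else 1.0
    return TargetedEstimate(psi, (float(eps[0]), float(eps[1])), D, se,
                            psi - Z975 * se, psi + Z975 * se, p,
                            q1_star, q0_star, frac_trunc, n)


# ---------------------------------------------------------------------------
# Nuisance estimation via super learning
# ---------------------------------------------------------------------------

@dataclass
class NuisanceFits:
    """Super-learner outcome and exposure mechanism predictions."""

    q0: np.ndarray
    q1: np.ndarray
    g: np.ndarray
    g_bounds: tuple[float, float]
    fraction_truncated: float
    outcome_fit: SuperLearnerFit | None = None
    exposure_fit: SuperLearnerFit | None = None


def fit_nuisances(
    df: pd.DataFrame,
    candidates: Sequence[CandidateSpec] | None = None,
    k: int = 10,
    loss: str = "log",
    g_bounds: tuple[float, float] = DEFAULT_G_BOUNDS,
    seed: int | None = None,
    confounders: Sequence[str] | None = None,
) -> NuisanceFits:
    """Fit Q(A,W) and g(W) by super learning on a complete data frame.

    The outcome mechanism is learned on [A, W]; counterfactual surfaces
    come from predicting with the exposure column set to 1 and to 0.  One
    stratified fold partition per mechanism is shared by all candidates.
    """
    candidates = list(candidates) if candidates is not None else reduced_library(
        0 if seed is None else seed)
    W, _ = confounder_design(df, confounders=list(confounders) if confounders else None)
    Wm = W.to_numpy(dtype=float)
    a = df[EXPOSURE].astype("boolean").to_numpy(dtype=float)
    y = df[OUTCOME].astype("boolean").to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(y).any():
        raise DataError("nuisance fitting requires complete exposure and outcome")

    Xq = np.column_stack([a, Wm])
    q_fit = fit_super_learner(candidates, Xq, y, k=k, loss=loss, seed=seed)
    X1 = Xq.copy(); X1[:, 0] = 1.0
    X0 = Xq.copy(); X0[:, 0] = 0.0
    q1 = sl_predict(q_fit, X1)
    q0 = sl_predict(q_fit, X0)

    g_fit = fit_super_learner(candidates, Wm, a, k=k, loss=loss,
                              seed=None if seed is None else seed + 1)
    g_raw = sl_predict(g_fit, Wm)
    g, frac = truncate_propensity(g_raw, *g_bounds)
    return NuisanceFits(q0, q1, g, g_bounds, frac, q_fit, g_fit)


# ---------------------------------------------------------------------------
# Robust pipeline: MI + SL + TMLE + Rubin
# ---------------------------------------------------------------------------

def robust_pipeline(
    imputation_set: ImputationSet,
    candidates: Sequence[CandidateSpec] | None = None,
    k: int = 10,
    loss: str = "log",
    g_bounds: tuple[float, float] = DEFAULT_G_BOUNDS,
    seed: int | None = None,
    confounders: Sequence[str] | None = None,
) -> tuple[PooledEstimate, list[dict]]:
    """TMLE with super-learner nuisances on each imputed dataset, pooled.

    Returns the Rubin-pooled ATU and one diagnostics record per imputed
    dataset (fluctuation coefficients, truncation fraction, ensemble CV
    risks).  The influence-curve variance is the within-imputation
    variance; between-imputation variance is carried by Rubin's B.
    """
    if imputation_set.m == 0:
        raise DataError("empty imputation set")
    pairs: list[tuple[float, float]] = []
    diagnostics: list[dict] = []
    for i, df in enumerate(imputation_set.completed):
        try:
            nuis = fit_nuisances(df, candidates, k=k, loss=loss,
                                 g_bounds=g_bounds,
                                 seed=None if seed is None else seed + 17 * i,
                                 confounders=confounders)
            a = df[EXPOSURE].astype("boolean").to_numpy(dtype=float)
            y = df[OUTCOME].astype("boolean").to_numpy(dtype=float)
            est = tmle_atu(a, y, nuis.q0, nuis.q1, nuis.g, g_bounds=None)
        except Exception as exc:
            raise type(exc)(f"imputation {i}: {exc}") from exc
        pairs.append((est.psi, est.se**2))
        diagnostics.append({
            "imputation": i,
            "psi": est.psi,
            "se": est.se,
            "epsilon": est.epsilon,
            "fraction_truncated": nuis.fraction_truncated,
            "outcome_sl": nuis.outcome_fit.summary() if nuis.outcome_fit else None,
            "exposure_sl": nuis.exposure_fit.summary() if nuis.exposure_fit else None,
        })
    n = len(imputation_set.completed[0])
    pooled = pool_rubin(pairs, df_complete=n - 1)
    return pooled, diagnostics
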