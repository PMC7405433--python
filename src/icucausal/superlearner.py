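"""Cross-validated stacking (super learner) for binary mechanisms.

Fits every candidate in a library on stratified K-fold training splits,
collects out-of-fold predicted probabilities, and chooses convex weights
over candidates minimizing an empirical risk: squared error (L2), log
loss, or rank loss (1 - AUC, midrank tie handling).  The L2 and log
problems are convex over the simplex and solved with SLSQP; rank loss is
not convex and uses multi-start local optimization seeded with the L2
solution.  The ensemble's CV risk never exceeds the best single
candidate's for the optimized loss (the best vertex is a fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError
from .learners import BaseCandidate, CandidateSpec

logger = logging.getLogger(__name__)

LOSSES = ("L2", "log", "rank")
_PCLIP = 1e-6


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """Stratified fold assignment: fold sizes and per-fold positive counts
    each differ by at most one."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ConfigError(f"need at least 2 folds, got {k}")
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    if k > minority:
        raise ConfigError(
            f"k={k} exceeds minority class count {minority}; stratification impossible")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=None if seed is None else int(seed) % 2**31)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


# ---------------------------------------------------------------------------
# Out-of-fold candidate predictions
# ---------------------------------------------------------------------------

def cv_predictions(
    candidates: Sequence[CandidateSpec],
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
) -> tuple[np.ndarray, list[bool]]:
    """Out-of-fold predicted probabilities, one column per candidate.

    Row i comes from models fitted without fold(i).  A candidate that
    fails on some training split has those rows filled with the training
    folds' outcome mean and is flagged; flagged candidates are excluded
    from the metalearner's weight support.
    """
    if len(candidates) == 0:
        raise ConfigError("no candidates")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty((n, len(candidates)))
    failed = [False] * len(candidates)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        for j, spec in enumerate(candidates):
            try:
                model = spec.build().fit(X[tr], y[tr])
                preds[te, j] = model.predict(X[te])
            except Exception as exc:
                if not failed[j]:
                    logger.warning("candidate %r failed on a CV split: %s",
                                   spec.name, exc)
                failed[j] = True
                preds[te, j] = y[tr].mean()
    if all(failed):
        raise DataError("all candidates failed in cross-validation")
    return np.clip(preds, 0.0, 1.0), failed


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _auc_midrank(p: np.ndarray, y: np.ndarray) -> float:
    """AUC with midrank tie correction."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return 0.5
    r = rankdata(p)  # average (mid) ranks
    return (r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def empirical_risk(p: np.ndarray, y: np.ndarray, loss: str) -> float:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if loss == "L2":
        return float(np.mean((y - p) ** 2))
    if loss == "log":
        q = np.clip(p, _PCLIP, 1 - _PCLIP)
        return float(-np.mean(y * np.log(q) + (1 - y) * np.log(1 - q)))
    if loss == "rank":
        return 1.0 - _auc_midrank(p, y)
    raise ConfigError(f"unknown loss {loss!r}")


# ---------------------------------------------------------------------------
# Metalearning over the simplex
# ---------------------------------------------------------------------------

def _project_simplex(w: np.ndarray) -> np.ndarray:
    w = np.maximum(w, 0)
    s = w.sum()
    return w / s if s > 0 else np.full_like(w, 1 / len(w))


def _optimize_convex(P, y, loss, support):
    k = P.shape[1]

    def risk(w):
        return empirical_risk(P @ w, y, loss)

    w0 = np.zeros(k)
    w0[support] = 1 / support.sum()
    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1}]
    bounds = [(0.0, 1.0) if s else (0.0, 0.0) for s in support]
    res = minimize(risk, w0, method="SLSQP", bounds=bounds, constraints=cons,
                   options={"maxiter": 300, "ftol": 1e-12})
    return _project_simplex(np.where(support, res.x, 0.0))


def _optimize_rank(P, y, support, seed, n_starts=20):
    k = P.shape[1]
    rng = np.random.default_rng(seed)
    starts = [_optimize_convex(P, y, "L2", support)]
    for _ in range(n_starts - 1):
        w = np.zeros(k)
        w[support] = rng.dirichlet(np.ones(int(support.sum())))
        starts.append(w)
    best_w, best_r = None, np.inf
    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1}]
    bounds = [(0.0, 1.0) if s else (0.0, 0.0) for s in support]

    def risk(w):
        return empirical_risk(P @ w, y, "rank")

    for w0 in starts:
        res = minimize(risk, w0, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"maxiter": 200, "ftol": 1e-10})
        w = _project_simplex(np.where(support, res.x, 0.0))
        r = risk(w)
        if r < best_r - 1e-12:
            best_w, best_r = w, r
    return best_w


def metalearn(
    cv_preds: np.ndarray,
    y: np.ndarray,
    loss: str = "log",
    failed: Sequence[bool] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Convex candidate weights minimizing the chosen empirical risk.

    Weights are non-negative, sum to one, and place no mass on failed
    candidates.  If the outcome is degenerate (single class) the weight
    goes to the first supported candidate (the null estimator by library
    convention) with a warning.
    """
    P = np.asarray(cv_preds, dtype=float)
    y = np.asarray(y, dtype=float)
    k = P.shape[1]
    support = np.asarray([not f for f in (failed or [False] * k)])
    if not support.any():
        raise DataError("no supported candidates")
    if len(np.unique(y)) < 2:
        logger.warning("degenerate outcome; weight 1 on first supported candidate")
        w = np.zeros(k)
        w[int(np.flatnonzero(support)[0])] = 1.0
        return w

    if loss == "rank":
        w = _optimize_rank(P, y, support, seed)
    else:
        w = _optimize_convex(P, y, loss, support)

    # dominance guarantee: never worse than the best single candidate
    vertex_risks = np.asarray(
        [empirical_risk(P[:, j], y, loss) if support[j] else np.inf
         for j in range(k)])
    j_best = int(np.argmin(vertex_risks))
    if empirical_risk(P @ w, y, loss) > vertex_risks[j_best] + 1e-12:
        w = np.zeros(k)
        w[j_best] = 1.0
    return w


# ---------------------------------------------------------------------------
# Super learner fit
# ---------------------------------------------------------------------------

@dataclass
class SuperLearnerFit:
    """Convex candidate weights plus refit full-data candidate models."""

    weights: np.ndarray
    loss: str
    candidate_names: list[str]
    cv_risks: dict[str, float]
    ensemble_cv_risk: float
    folds: np.ndarray
    models: list[BaseCandidate | None]
    failed: list[bool]
    cv_preds: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "loss": self.loss,
            "weights": {n: float(w) for n, w in
                        zip(self.candidate_names, self.weights)},
            "cv_risks": self.cv_risks,
            "ensemble_cv_risk": self.ensemble_cv_risk,
            "failed": {n: f for n, f in zip(self.candidate_names, self.failed)},
        }


def fit_super_learner(
    candidates: Sequence[CandidateSpec],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    loss: str = "log",
    seed: int | None = None,
    folds: np.ndarray | None = None,
    keep_cv_preds: bool = False,
) -> SuperLearnerFit:
    """Full super-learner fit: CV weights + candidates refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds is None:
        folds = stratified_folds(y, k, seed)
    preds, failed = cv_predictions(candidates, X, y, folds)
    w = metalearn(preds, y, loss=loss, failed=failed, seed=seed)
    models: list[BaseCandidate | None] = []
    for j, spec in enumerate(candidates):
        if failed[j] or w[j] == 0.0:
            models.append(None)
            continue
        try:
            models.append(spec.build().fit(X, y))
        except Exception:
            models.append(None)
            failed[j] = True
            w[j] = 0.0
    if w.sum() == 0:
        raise DataError("every weighted candidate failed on the full data")
    w = w / w.sum()
    cv_risks = {spec.name: empirical_risk(preds[:, j], y, loss)
                for j, spec in enumerate(candidates)}
    return SuperLearnerFit(
        weights=w, loss=loss, candidate_names=[c.name for c in candidates],
        cv_risks=cv_risks, ensemble_cv_risk=empirical_risk(preds @ w, y, loss),
        folds=folds, models=models, failed=failed,
        cv_preds=preds if keep_cv_preds else None)


def sl_predict(fit: SuperLearnerFit, X: np.ndarray) -> np.ndarray:
    """Weighted combination of full-data candidate predictions in [0, 1]."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(len(X))
    used = 0.0
    for w, model in zip(fit.weights, fit.models):
        if w == 0.0 or model is None:
            continue
        if not model.fitted:
            raise DataError("unfitted candidate in super learner")
        out += w * model.predict(X)
        used += w
    if used == 0:
        raise DataError("super learner has no usable candidates")
    return np.clip(out / used, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

def nested_cv_performance(
    candidates: Sequence[CandidateSpec],
    X: np.ndarray,
    y: np.ndarray,
    k_outer: int = 5,
    k_inner: int = 10,
    losses: Sequence[str] = LOSSES,
    seed: int | None = None,
):
    """Outer-fold-averaged risks for each candidate and each metalearner.

    Returns a DataFrame with one row per candidate plus one per ensemble
    ('sl_<loss>'), one column per evaluation loss.  Used to pick the
    operating loss for the targeting step.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    outer = stratified_folds(y, k_outer, seed)
    names = [c.name for c in candidates] + [f"sl_{l}" for l in losses]
    sums = {n: {l: 0.0 for l in losses} for n in names}
    counts = {n: 0 for n in names}
    for f in np.unique(outer):
        tr, te = outer != f, outer == f
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
        inner_folds = stratified_folds(ytr, k_inner,
                                       None if seed is None else seed + 1000 + f)
        preds_tr, failed = cv_predictions(candidates, Xtr, ytr, inner_folds)
        # candidate test-risk: refit on full outer-training data
        for j, spec in enumerate(candidates):
            try:
                p_te = spec.build().fit(Xtr, ytr).predict(Xte)
            except Exception:
                p_te = np.full(int(te.sum()), ytr.mean())
            for l in losses:
                sums[spec.name][l] += empirical_risk(p_te, yte, l)
            counts[spec.name] += 1
        for l in losses:
            w = metalearn(preds_tr, ytr, loss=l, failed=failed, seed=seed)
            p_te = np.zeros(int(te.sum()))
            used = 0.0
            for j, spec in enumerate(candidates):
                if w[j] == 0.0:
                    continue
                try:
                    p_te += w[j] * spec.build().fit(Xtr, ytr).predict(Xte)
                    used += w[j]
                except Exception:
                    continue
            p_te = p_te / used if used > 0 else np.full(int(te.sum()), ytr.mean())
            for l2 in losses:
                sums[f"sl_{l}"][l2] += empirical_risk(p_te, yte, l2)
            counts[f"sl_{l}"] += 1
    rows = {n: {l: sums[n][l] / max(counts[n], 1) for l in losses} for n in names}
    return pd.DataFrame(rows).T[list(losses)]
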