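"""Candidate learner registry for the super learner.

Fifteen candidates for binary risk prediction: null estimator
(unconditional mean), main-effects logistic regression, stepwise (AIC)
logistic regression, five elastic-net logistic regressions with mixing
parameter 0 (ridge), 0.25, 0.5, 0.75 and 1 (lasso), random forest,
extreme gradient boosting, a support vector machine with Platt-scaled
probabilities, an additive tree ensemble (shallow gradient-boosted
stumps), and three additive polynomial logistic models of degree 2, 3 and
4 on the continuous features.

Every candidate exposes ``fit(X, y)`` and ``predict(X) -> p in [0, 1]``
and is deterministic given its seed.  A reduced four-candidate library
(null, main-effects logistic, ridge, gradient boosting) is provided for
fast pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

_CLIP = 1e-6


def _clip01(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


@dataclass
class CandidateSpec:
    """Name + family tag + hyperparameters of one candidate algorithm."""

    name: str
    family: str
    hyperparameters: dict[str, Any] = dc_field(default_factory=dict)
    seed: int = 0

    def build(self) -> "BaseCandidate":
        cls = _FAMILIES[self.family]
        return cls(self)


class BaseCandidate:
    def __init__(self, spec: CandidateSpec):
        self.spec = spec
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseCandidate":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class NullMean(BaseCandidate):
    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        self.fitted = True
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _SkWrapper(BaseCandidate):
    def _make(self):
        raise NotImplementedError

    def fit(self, X, y):
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate outcome for this candidate")
        self.model_ = self._make()
        self.model_.fit(X, y)
        self.fitted = True
        return self

    def predict(self, X):
        return _clip01(self.model_.predict_proba(X)[:, 1])


class MainEffectsLogistic(_SkWrapper):
    def _make(self):
        return LogisticRegression(C=np.inf, max_iter=2000)


class ElasticNetLogistic(_SkWrapper):
    def _make(self):
        hp = self.spec.hyperparameters
        return LogisticRegression(
            solver="saga", l1_ratio=hp.get("l1_ratio", 0.5),
            C=hp.get("C", 1.0), max_iter=5000, tol=1e-5,
            random_state=self.spec.seed)


class RandomForest(_SkWrapper):
    def _make(self):
        hp = self.spec.hyperparameters
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 300),
            min_samples_leaf=hp.get("min_samples_leaf", 5),
            random_state=self.spec.seed, n_jobs=1)


class ExtremeGradientBoosting(_SkWrapper):
    def _make(self):
        hp = self.spec.hyperparameters
        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.1),
            subsample=hp.get("subsample", 0.8),
            colsample_bytree=hp.get("colsample_bytree", 0.8),
            reg_lambda=hp.get("reg_lambda", 1.0),
            random_state=self.spec.seed, n_jobs=1,
            eval_metric="logloss", verbosity=0)


class SupportVector(_SkWrapper):
    """RBF support vector machine with Platt-scaled probabilities."""

    def _make(self):
        from sklearn.calibration import CalibratedClassifierCV

        hp = self.spec.hyperparameters
        svc = SVC(C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                  random_state=self.spec.seed)
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                      ensemble=False)


class AdditiveTreeEnsemble(_SkWrapper):
    """Shallow boosted trees: an additive expansion in small trees."""

    def _make(self):
        hp = self.spec.hyperparameters
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", 2),
            learning_rate=hp.get("learning_rate", 0.05),
            random_state=self.spec.seed)


def _continuous_columns(X: np.ndarray, max_levels: int = 12) -> np.ndarray:
    return np.asarray([len(np.unique(X[:, j])) > max_levels
                       for j in range(X.shape[1])])


class PolynomialLogistic(BaseCandidate):
    """Additive polynomial expansion of the continuous columns, then
    unpenalized logistic regression (a parametric additive model)."""

    def _expand(self, X):
        degree = self.spec.hyperparameters.get("degree", 2)
        parts = [X]
        for d in range(2, degree + 1):
            parts.append(X[:, self.cont_] ** d)
        return np.column_stack(parts)

    def fit(self, X, y):
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate outcome for this candidate")
        self.cont_ = _continuous_columns(X)
        self.model_ = LogisticRegression(C=np.inf, max_iter=2000)
        self.model_.fit(self._expand(X), y)
        self.fitted = True
        return self

    def predict(self, X):
        return _clip01(self.model_.predict_proba(self._expand(X))[:, 1])


class StepwiseLogistic(BaseCandidate):
    """Bidirectional AIC stepwise logistic regression.

    A prediction algorithm inside cross-validation, not cohort-level model
    selection; the traditional arm never drops covariates.
    """

    def _aic(self, X1, y, cols):
        Xs = X1[:, [0] + [c + 1 for c in cols]]
        try:
            res = sm.GLM(y, Xs, family=sm.families.Binomial()).fit(maxiter=50)
            return res.aic, res
        except Exception:
            return np.inf, None

    def fit(self, X, y):
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate outcome for this candidate")
        n, p = X.shape
        X1 = np.column_stack([np.ones(n), X])
        selected: list[int] = []
        best_aic, best_res = self._aic(X1, y, selected)
        max_steps = self.spec.hyperparameters.get("max_steps", 2 * p)
        for _ in range(max_steps):
            moves = [selected + [j] for j in range(p) if j not in selected]
            moves += [[c for c in selected if c != j] for j in selected]
            improved = False
            for cols in moves:
                aic, res = self._aic(X1, y, cols)
                if aic < best_aic - 1e-9:
                    best_aic, best_res, selected = aic, res, cols
                    improved = True
            if not improved:
                break
        self.cols_, self.res_ = selected, best_res
        self.fitted = True
        return self

    def predict(self, X):
        X1 = np.column_stack([np.ones(len(X)), X])
        Xs = X1[:, [0] + [c + 1 for c in self.cols_]]
        return _clip01(self.res_.predict(Xs))


_FAMILIES: dict[str, type[BaseCandidate]] = {
    "null-mean": NullMean,
    "main-effects-logistic": MainEffectsLogistic,
    "stepwise-logistic": StepwiseLogistic,
    "elastic-net": ElasticNetLogistic,
    "random-forest": RandomForest,
    "gradient-boosting": ExtremeGradientBoosting,
    "support-vector": SupportVector,
    "additive-tree-ensemble": AdditiveTreeEnsemble,
    "additive-polynomial": PolynomialLogistic,
}


def full_library(seed: int = 0) -> list[CandidateSpec]:
    """The 15-candidate library."""
    specs = [
        CandidateSpec("null", "null-mean"),
        CandidateSpec("logistic_main", "main-effects-logistic"),
        CandidateSpec("logistic_stepwise", "stepwise-logistic"),
    ]
    for mix in (0.0, 0.25, 0.5, 0.75, 1.0):
        specs.append(CandidateSpec(f"elasticnet_{mix:g}", "elastic-net",
                                   {"l1_ratio": mix}, seed))
    specs += [
        CandidateSpec("random_forest", "random-forest", {}, seed),
        CandidateSpec("xgboost", "gradient-boosting", {}, seed),
        CandidateSpec("svm", "support-vector", {}, seed),
        CandidateSpec("additive_trees", "additive-tree-ensemble", {}, seed),
        CandidateSpec("gam_poly2", "additive-polynomial", {"degree": 2}),
        CandidateSpec("gam_poly3", "additive-polynomial", {"degree": 3}),
        CandidateSpec("gam_poly4", "additive-polynomial", {"degree": 4}),
    ]
    return specs


def reduced_library(seed: int = 0) -> list[CandidateSpec]:
    """Fast four-candidate library for tests and scaled-down pipelines."""
    return [
        CandidateSpec("null", "null-mean"),
        CandidateSpec("logistic_main", "main-effects-logistic"),
        CandidateSpec("elasticnet_0", "elastic-net", {"l1_ratio": 0.0}, seed),
        CandidateSpec("xgboost", "gradient-boosting",
                      {"n_estimators": 80, "max_depth": 3}, seed),
    ]
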