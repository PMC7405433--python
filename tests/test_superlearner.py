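"""Super learner: folds, out-of-fold predictions, metalearning, nesting."""

import numpy as np
import pytest
from scipy.special import expit

from icucausal.errors import ConfigError, DataError
from icucausal.learners import CandidateSpec, full_library, reduced_library
from icucausal.superlearner import (
    cv_predictions,
    empirical_risk,
    fit_super_learner,
    metalearn,
    nested_cv_performance,
    sl_predict,
    stratified_folds,
)


def _logistic_world(n, seed, p=5):
    rng = np.random.default_rng(seed)
    beta = np.array([0.8, -0.5, 0.3, 0.0, 0.4])[:p]
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < expit(-1.0 + X @ beta)).astype(float)
    return X, y


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            m = folds == f
            assert m.sum() == 10
            assert y[m].sum() == 2

    def test_uneven_positives_split_evenly(self):
        y = np.array([1] * 23 + [0] * 77)
        folds = stratified_folds(y, 10, seed=1)
        pos_counts = sorted(int(y[folds == f].sum()) for f in range(10))
        assert pos_counts == [2] * 7 + [3] * 3
        sizes = [int((folds == f).sum()) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1

    def test_invalid_k_rejected(self):
        y = np.array([1, 0] * 10)
        with pytest.raises(ConfigError):
            stratified_folds(y, 1)
        with pytest.raises(ConfigError):
            stratified_folds(y, 11)  # more folds than minority count


class TestCvPredictions:
    def test_null_candidate_returns_training_fold_mean(self):
        X, y = _logistic_world(60, 2)
        folds = stratified_folds(y, 3, seed=2)
        preds, failed = cv_predictions([CandidateSpec("null", "null-mean")],
                                       X, y, folds)
        assert not any(failed)
        for f in range(3):
            m = folds == f
            assert np.allclose(preds[m, 0], y[~m].mean())

    def test_matches_manual_two_fold_fit(self):
        X, y = _logistic_world(60, 3)
        spec = CandidateSpec("logistic_main", "main-effects-logistic")
        folds = stratified_folds(y, 2, seed=3)
        preds, _ = cv_predictions([spec], X, y, folds)
        for f in (0, 1):
            te = folds == f
            manual = spec.build().fit(X[~te], y[~te]).predict(X[te])
            assert np.allclose(preds[te, 0], manual)

    def test_memorizing_candidate_cannot_leak(self):
        class Memorizer:
            """1-nearest-neighbour on a unique key: perfect in-sample."""
            fitted = False

            def fit(self, X, y):
                self.key_, self.y_ = X[:, 0], y
                self.fitted = True
                return self

            def predict(self, X):
                idx = np.abs(X[:, 0][:, None] - self.key_[None, :]).argmin(axis=1)
                return self.y_[idx]

        class MemorizerSpec(CandidateSpec):
            def build(self):
                return Memorizer()

        n = 200
        rng = np.random.default_rng(4)
        X = np.arange(n, dtype=float).reshape(-1, 1)  # unique key column
        y = (rng.random(n) < 0.5).astype(float)
        folds = stratified_folds(y, 4, seed=4)
        preds, _ = cv_predictions([MemorizerSpec("memo", "null-mean")], X, y, folds)
        accuracy = np.mean((preds[:, 0] > 0.5) == y)
        assert accuracy < 0.65  # out-of-fold predictions cannot reproduce y

    def test_failing_candidate_filled_and_flagged(self):
        class Exploder(CandidateSpec):
            def build(self):
                raise RuntimeError("boom")

        X, y = _logistic_world(60, 5)
        folds = stratified_folds(y, 3, seed=5)
        preds, failed = cv_predictions(
            [Exploder("bad", "null-mean"), CandidateSpec("null", "null-mean")],
            X, y, folds)
        assert failed == [True, False]
        for f in range(3):
            m = folds == f
            assert np.allclose(preds[m, 0], y[~m].mean())
        with pytest.raises(DataError):
            cv_predictions([Exploder("bad", "null-mean")], X, y, folds)


class TestMetalearn:
    def test_single_candidate_gets_weight_one(self):
        X, y = _logistic_world(80, 6)
        preds = np.full((80, 1), y.mean())
        for loss in ("L2", "log", "rank"):
            w = metalearn(preds, y, loss=loss, seed=0)
            assert np.allclose(w, [1.0])

    @pytest.mark.parametrize("loss", ["L2", "log", "rank"])
    def test_perfect_predictor_dominates(self, loss):
        _, y = _logistic_world(100, 7)
        perfect = np.clip(y, 0.01, 0.99)
        noise = np.full(100, y.mean())
        w = metalearn(np.column_stack([perfect, noise]), y, loss=loss, seed=0)
        assert w[0] > 0.95

    def test_l2_matches_simplex_grid_search(self):
        rng = np.random.default_rng(8)
        _, y = _logistic_world(50, 8)
        p1 = np.clip(y * 0.7 + rng.uniform(0, 0.3, 50), 0, 1)
        p2 = np.clip(rng.uniform(0.2, 0.8, 50), 0, 1)
        P = np.column_stack([p1, p2])
        w = metalearn(P, y, loss="L2")
        grid = np.arange(0, 1.0005, 0.001)
        risks = [empirical_risk(P @ np.array([a, 1 - a]), y, "L2") for a in grid]
        a_best = grid[int(np.argmin(risks))]
        assert abs(w[0] - a_best) < 0.01

    def test_degenerate_outcome_falls_back_to_first_candidate(self):
        y = np.ones(30)
        preds = np.column_stack([np.full(30, 0.5), np.full(30, 0.9)])
        w = metalearn(preds, y, loss="log")
        assert np.allclose(w, [1.0, 0.0])

    def test_weights_valid_and_dominant(self):
        X, y = _logistic_world(300, 9)
        folds = stratified_folds(y, 5, seed=9)
        preds, failed = cv_predictions(reduced_library(9), X, y, folds)
        for loss in ("L2", "log", "rank"):
            w = metalearn(preds, y, loss=loss, failed=failed, seed=9)
            assert np.all(w >= 0)
            assert abs(w.sum() - 1) < 1e-9
            ens = empirical_risk(preds @ w, y, loss)
            best_vertex = min(empirical_risk(preds[:, j], y, loss)
                              for j in range(preds.shape[1]))
            assert ens <= best_vertex + 1e-9


class TestSlPredict:
    def test_degenerate_weights_reduce_to_candidate(self):
        X, y = _logistic_world(120, 10)
        fit = fit_super_learner(
            [CandidateSpec("null", "null-mean"),
             CandidateSpec("logistic_main", "main-effects-logistic")],
            X, y, k=3, loss="L2", seed=10)
        fit.weights = np.array([1.0, 0.0])
        assert np.allclose(sl_predict(fit, X), y.mean())

    def test_constant_candidates_average(self):
        class Const(CandidateSpec):
            def build(self):
                value = self.hyperparameters["value"]

                class _C:
                    fitted = False

                    def fit(self, X, y):
                        self.fitted = True
                        return self

                    def predict(self, X):
                        return np.full(len(X), value)

                return _C()

        X, y = _logistic_world(50, 11)
        fit = fit_super_learner(
            [Const("c2", "null-mean", {"value": 0.2}),
             Const("c6", "null-mean", {"value": 0.6})],
            X, y, k=2, loss="L2", seed=11)
        fit.weights = np.array([0.5, 0.5])
        assert np.allclose(sl_predict(fit, X), 0.4)

    def test_predictions_in_unit_interval(self):
        X, y = _logistic_world(200, 12)
        fit = fit_super_learner(reduced_library(12), X, y, k=4, loss="log", seed=12)
        p = sl_predict(fit, X)
        assert p.min() >= 0 and p.max() <= 1


class TestFitSuperLearner:
    def test_deterministic_given_seed(self):
        X, y = _logistic_world(300, 13)
        f1 = fit_super_learner(reduced_library(13), X, y, k=5, loss="log", seed=13)
        f2 = fit_super_learner(reduced_library(13), X, y, k=5, loss="log", seed=13)
        assert np.array_equal(f1.weights, f2.weights)
        assert np.array_equal(f1.folds, f2.folds)

    def test_full_library_runs_and_is_valid(self):
        X, y = _logistic_world(300, 14)
        fit = fit_super_learner(full_library(14), X, y, k=3, loss="log", seed=14)
        assert len(fit.weights) == 15
        assert abs(fit.weights.sum() - 1) < 1e-9
        assert not all(fit.failed)
        assert fit.ensemble_cv_risk <= min(
            r for r, f in zip(fit.cv_risks.values(), fit.failed) if not f) + 1e-9

    def test_weight_concentrates_on_true_family(self):
        # in a logistic world the logistic-family weight (unpenalized +
        # ridge) should grow with n and approach one
        mean_w = {}
        for n in (500, 2000, 8000):
            ws = []
            for s in range(10):
                X, y = _logistic_world(n, 1000 + s)
                fit = fit_super_learner(reduced_library(7), X, y, k=10,
                                        loss="log", seed=s)
                w = dict(zip(fit.candidate_names, fit.weights))
                ws.append(w["logistic_main"] + w["elasticnet_0"])
            mean_w[n] = float(np.mean(ws))
        assert mean_w[2000] > mean_w[500]
        assert mean_w[8000] > mean_w[500]
        assert mean_w[8000] > 0.85
        # allow Monte-Carlo dither near the plateau
        assert mean_w[8000] > mean_w[2000] - 0.03


class TestNestedCv:
    def test_single_candidate_nested_equals_plain_cv(self):
        X, y = _logistic_world(100, 15)
        y[:40] = 1.0
        y[40:] = 0.0  # 40/60 split, divisible by 5 folds
        spec = CandidateSpec("logistic_main", "main-effects-logistic")
        table = nested_cv_performance([spec], X, y, k_outer=5, k_inner=2,
                                      losses=("L2", "log"), seed=15)
        folds = stratified_folds(y, 5, seed=15)
        preds, _ = cv_predictions([spec], X, y, folds)
        for loss in ("L2", "log"):
            plain = empirical_risk(preds[:, 0], y, loss)
            assert table.loc["logistic_main", loss] == pytest.approx(plain, rel=1e-9)

    def test_logistic_candidate_near_optimal_in_logistic_world(self):
        X, y = _logistic_world(4000, 16)
        table = nested_cv_performance(reduced_library(16), X, y, k_outer=3,
                                      k_inner=5, losses=("log",), seed=16)
        candidate_rows = [c.name for c in reduced_library(16)]
        best = table.loc[candidate_rows, "log"].idxmin()
        assert best in ("logistic_main", "elasticnet_0")

    def test_table_shape_and_finiteness(self):
        X, y = _logistic_world(200, 17)
        table = nested_cv_performance(reduced_library(17), X, y, k_outer=3,
                                      k_inner=3, seed=17)
        assert list(table.columns) == ["L2", "log", "rank"]
        assert len(table) == 4 + 3  # candidates + three ensembles
        assert np.isfinite(table.to_numpy()).all()
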