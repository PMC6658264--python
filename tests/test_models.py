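"""Model-family contracts: baseline, elastic net, trees, ensembles, and the
explicit-weight networks, plus grid search bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from stresscast import models as mdl
from tests.conftest import make_regression_frame


def linear_problem(n=100, d=4, noise=0.0, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = X @ w + (rng.normal(0, noise, n) if noise else 0.0)
    return X, y, w


class TestBaseline:
    def _frame(self, y, pid="p0"):
        return make_regression_frame(np.zeros((len(y), 1)), y, person_id=pid)

    def test_predicts_training_median(self):
        model = mdl.train_baseline(self._frame([0, 10, 2]))
        assert np.all(model.predict(self._frame([0, 0, 0])) == 2.0)

    def test_single_sample(self):
        model = mdl.train_baseline(self._frame([5]))
        assert model.predict(self._frame([0]))[0] == 5.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            mdl.train_baseline(self._frame([]))

    def test_binarized_baseline_is_always_class_zero(self):
        # median > median is false under the tie rule
        from stresscast import features as feat

        train = self._frame([1, 3, 3, 7, 2])
        model = mdl.train_baseline(train)
        th = feat.compute_thresholds(train)["p0"]
        classes = feat.binarize(model.predict(train), th)
        assert np.all(classes == 0)

    def test_unseen_person_gets_pooled_median(self):
        model = mdl.train_baseline(self._frame([1, 2, 9]))
        other = self._frame([0], pid="stranger")
        assert model.predict(other)[0] == 2.0


class TestElasticNet:
    def test_unpenalized_fit_recovers_coefficients(self):
        X, y, w = linear_problem(noise=0.0)
        model = mdl.train_elastic_net(make_regression_frame(X, y),
                                      [f"f{i}" for i in range(4)], alpha=0.0)
        assert np.allclose(model.predictor.coef_, w, atol=1e-6)

    def test_infinite_penalty_predicts_training_mean(self):
        X, y, _ = linear_problem(noise=0.5)
        model = mdl.train_elastic_net(make_regression_frame(X, y),
                                      [f"f{i}" for i in range(4)], alpha=1e6)
        assert np.allclose(model.predictor.coef_, 0.0)
        assert np.allclose(model.predict(make_regression_frame(X, y)), y.mean())

    def test_lasso_zeroes_irrelevant_feature(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = 2.0 * X[:, 0] + 1.0 * X[:, 1]  # f2 irrelevant
        model = mdl.train_elastic_net(make_regression_frame(X, y),
                                      ["f0", "f1", "f2"], alpha=0.1, l1_ratio=1.0)
        assert model.predictor.coef_[2] == 0.0
        assert abs(model.predictor.coef_[0]) > 1.0

    def test_nonfinite_features_rejected(self):
        X, y, _ = linear_problem()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mdl.train_elastic_net(make_regression_frame(X, y),
                                  [f"f{i}" for i in range(4)])


class TestTree:
    def test_step_function_gives_full_importance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3))
        y = (X[:, 1] > 0).astype(float) * 4.0
        model = mdl.train_tree(make_regression_frame(X, y), ["f0", "f1", "f2"],
                               max_depth=2, min_samples_leaf=2)
        imp = model.importances()
        assert imp[1] == pytest.approx(1.0)

    def test_constant_target_single_leaf(self):
        X = np.random.default_rng(5).normal(size=(30, 2))
        y = np.full(30, 4.0)
        model = mdl.train_tree(make_regression_frame(X, y), ["f0", "f1"])
        assert np.all(model.importances() == 0.0)
        assert np.all(model.predict(make_regression_frame(X, y)) == 4.0)

    def test_stump_threshold_matches_bruteforce_best_split(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.normal(size=20))
        y = rng.normal(size=20)
        frame = make_regression_frame(x[:, None], y)
        model = mdl.train_tree(frame, ["f0"], max_depth=1, min_samples_leaf=1)

        def sse(v):
            return ((v - v.mean()) ** 2).sum() if len(v) else 0.0

        best_gain, best_threshold = -np.inf, None
        for i in range(1, 20):  # candidate thresholds: midpoints
            thr = (x[i - 1] + x[i]) / 2
            gain = sse(y) - sse(y[x <= thr]) - sse(y[x > thr])
            if gain > best_gain:
                best_gain, best_threshold = gain, thr
        tree = model.predictor.tree_
        assert tree.threshold[0] == pytest.approx(best_threshold)


class TestEnsembles:
    def test_single_tree_forest_reduces_to_tree(self):
        X, y, _ = linear_problem(noise=0.3, seed=7)
        frame = make_regression_frame(X, y)
        names = [f"f{i}" for i in range(4)]
        tree = mdl.train_tree(frame, names, max_depth=3, min_samples_leaf=2)
        forest = mdl.train_ensemble(frame, names, "random_forest", n_estimators=1,
                                    bootstrap=False, max_features=None,
                                    max_depth=3, min_samples_leaf=2)
        assert np.allclose(tree.predict(frame), forest.predict(frame))

    def test_single_stage_unit_shrinkage_gbt_reduces_to_tree(self):
        X, y, _ = linear_problem(noise=0.3, seed=8)
        frame = make_regression_frame(X, y)
        names = [f"f{i}" for i in range(4)]
        tree = mdl.train_tree(frame, names, max_depth=3, min_samples_leaf=2)
        gbt = mdl.train_ensemble(frame, names, "gbt", n_estimators=1,
                                 learning_rate=1.0, max_depth=3, min_samples_leaf=2)
        assert np.allclose(tree.predict(frame), gbt.predict(frame))

    def test_forest_beats_single_tree_on_average(self):
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 5))
            y = X[:, 0] * X[:, 1] + X[:, 2] + rng.normal(0, 0.5, 120)
            train, test = (
                make_regression_frame(X[:80], y[:80]),
                make_regression_frame(X[80:], y[80:]),
            )
            names = [f"f{i}" for i in range(5)]
            tree = mdl.train_tree(train, names, max_depth=5, min_samples_leaf=2,
                                  seed=seed)
            forest = mdl.train_ensemble(train, names, "random_forest",
                                        n_estimators=50, max_depth=5,
                                        min_samples_leaf=2, max_features=0.6,
                                        seed=seed)
            err_t = np.abs(tree.predict(test) - y[80:]).mean()
            err_f = np.abs(forest.predict(test) - y[80:]).mean()
            deltas.append(err_t - err_f)
        assert np.mean(deltas) > 0

    def test_unknown_family_rejected(self):
        X, y, _ = linear_problem()
        with pytest.raises(ValueError):
            mdl.train_ensemble(make_regression_frame(X, y),
                               [f"f{i}" for i in range(4)], "boosted_stump")


class TestMLP:
    def test_zero_hidden_layers_match_least_squares(self):
        X, y, _ = linear_problem(n=100, noise=0.0, seed=9)
        frame = make_regression_frame(X, y)
        names = [f"f{i}" for i in range(4)]
        model = mdl.train_mlp(frame, names, hidden=(), dropout_rate=0.0,
                              bias_mode="free", seed=0, epochs=2000, lr=0.02,
                              val_fraction=0.0)
        beta = np.linalg.lstsq(np.c_[X, np.ones(len(X))], y, rcond=None)[0]
        oracle = np.c_[X, np.ones(len(X))] @ beta
        assert np.max(np.abs(model.predict(frame) - oracle)) < 1e-3

    def test_fixed_seed_training_is_reproducible(self):
        X, y, _ = linear_problem(noise=0.2, seed=10)
        frame = make_regression_frame(X, y)
        names = [f"f{i}" for i in range(4)]
        runs = [
            mdl.train_mlp(frame, names, hidden=(8,), dropout_rate=0.2, seed=3,
                          epochs=30)
            for _ in range(2)
        ]
        for w1, w2 in zip(runs[0].predictor.weights, runs[1].predictor.weights):
            assert np.array_equal(w1, w2)

    def test_locked_zero_biases_stay_zero(self):
        X, y, _ = linear_problem(noise=0.2, seed=11)
        model = mdl.train_mlp(make_regression_frame(X, y),
                              [f"f{i}" for i in range(4)], hidden=(8,),
                              bias_mode="locked_zero", seed=0, epochs=50)
        for b in model.predictor.biases:
            assert np.all(b == 0.0)

    def test_capacity_beats_baseline_on_rectified_target(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 3))
        y = np.maximum(0.0, 2.0 * X[:, 0])
        frame = make_regression_frame(X, y)
        names = ["f0", "f1", "f2"]
        model = mdl.train_mlp(frame[:200], names, hidden=(16,), dropout_rate=0.0,
                              seed=0, epochs=400, val_fraction=0.0)
        pred = model.predict(frame[200:])
        mae_net = np.abs(pred - y[200:]).mean()
        mae_baseline = np.abs(np.median(y[:200]) - y[200:]).mean()
        assert mae_net < mae_baseline

    def test_zero_bias_network_is_positively_homogeneous(self):
        rng = np.random.default_rng(13)
        net = mdl.LayerStack.init([5, 8, 4, 1], "locked_zero", rng)
        for _ in range(50):
            x = rng.normal(size=5)
            c = float(rng.uniform(0.1, 10.0))
            assert net.predict(c * x)[0] == pytest.approx(c * net.predict(x)[0])

    def test_nonfinite_loss_aborts_with_message(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        y = np.full(50, np.inf)  # squared-error loss is immediately non-finite
        with pytest.raises(mdl.DivergenceError, match="non-finite"):
            mdl.train_mlp(make_regression_frame(X, y), ["f0", "f1"], hidden=(4,),
                          seed=0, epochs=10, val_fraction=0.0)


class TestRNN:
    seq_cols = [f"stress_lag{k}" for k in (1, 2, 3)] + [
        f"tavg_f_lag{k}" for k in (1, 2, 3)
    ]

    def test_passthrough_single_step_equals_mlp(self):
        # Wh = 0 makes the RNN a one-hidden-layer MLP of the last step
        rng = np.random.default_rng(14)
        cols = ["stress_lag1", "tavg_f_lag1", "age"]
        layout = mdl.sequence_layout(cols)
        assert layout["lags"] == [1]
        net = mdl.RecurrentNet.init(layout, 6, "locked_zero", rng)
        net.Wh[...] = 0.0
        d_static = len(layout["static_indices"])
        stack = mdl.LayerStack(
            [net.Wx, net.Wout[:6]], [np.zeros(6), np.zeros(1)], "locked_zero"
        )
        for _ in range(20):
            x = rng.normal(size=3)
            step = x[layout["step_indices"][0]]
            static = x[layout["static_indices"]]
            expected = stack.predict(step)[0] + float(static @ net.Wout[6:, 0])
            assert net.predict(x)[0] == pytest.approx(expected)

    def test_fixed_seed_training_is_reproducible(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 6))
        y = rng.normal(size=60)
        df = make_regression_frame(X, y)
        df.columns = self.seq_cols + list(df.columns[6:])
        runs = [
            mdl.train_rnn(df, self.seq_cols, hidden_size=4, seed=2, epochs=20)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].predictor.Wx, runs[1].predictor.Wx)
        assert np.array_equal(runs[0].predictor.Wout, runs[1].predictor.Wout)

    def test_learns_autoregressive_structure(self):
        rng = np.random.default_rng(16)
        n = 400
        X = rng.normal(size=(n, 6))
        y = 0.9 * X[:, 0] + 0.2 * X[:, 1] + rng.normal(0, 0.3, n)
        df = make_regression_frame(X, y)
        df.columns = self.seq_cols + list(df.columns[6:])
        model = mdl.train_rnn(df[:300], self.seq_cols, hidden_size=8,
                              dropout_rate=0.0, seed=0, epochs=300,
                              val_fraction=0.0)
        mae_net = np.abs(model.predict(df[300:]) - y[300:]).mean()
        mae_baseline = np.abs(np.median(y[:300]) - y[300:]).mean()
        assert mae_net < mae_baseline


class TestGridSearch:
    def _frame(self, n=60, seed=17):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = 2 * X[:, 0] + rng.normal(0, 0.3, n)
        return make_regression_frame(X, y), ["f0", "f1", "f2"]

    def test_single_point_grid_returns_it(self):
        frame, names = self._frame()
        best, table = mdl.grid_search(
            mdl.train_elastic_net, {"alpha": [0.01]}, frame, feature_names=names
        )
        assert best == {"alpha": 0.01}

    def test_degenerate_point_loses_to_informative_point(self):
        frame, names = self._frame()
        best, _ = mdl.grid_search(
            mdl.train_elastic_net, {"alpha": [1e9, 0.01]}, frame,
            feature_names=names,
        )
        assert best == {"alpha": 0.01}

    def test_every_grid_point_scored_on_every_fold(self):
        frame, names = self._frame()
        grid = {"alpha": [0.001, 0.01, 0.1], "l1_ratio": [0.2, 0.8]}
        _, table = mdl.grid_search(mdl.train_elastic_net, grid, frame, k=3,
                                   feature_names=names)
        assert len(table) == 6 * 3
        assert (table.groupby("combo_index")["fold"].count() == 3).all()

    def test_tie_prefers_earliest_grid_point(self):
        frame, names = self._frame()
        # duplicated grid point: identical CV scores, first one must win
        best, _ = mdl.grid_search(
            mdl.train_elastic_net, [{"alpha": 0.05}, {"alpha": 0.05}], frame,
            feature_names=names,
        )
        assert best is not None  # returns the first of the tied combos

    def test_too_few_samples_for_folds_rejected(self):
        frame, names = self._frame(n=2)
        with pytest.raises(ValueError):
            mdl.grid_search(mdl.train_elastic_net, {"alpha": [0.1]}, frame, k=3,
                            feature_names=names)
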