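"""Model families under a uniform contract.

All models produce a continuous stress prediction for a lagged sample and, per
family, expose an attribution hook: coefficients for the elastic net, impurity
importances for trees and ensembles, and explicit layer weights for the neural
networks so that relevance propagation can traverse them.

The elastic net, decision tree, random forest, and gradient-boosted trees are
standard scikit-learn fits.  The multilayer perceptron and the recurrent
network are explicit-weight numpy implementations: layer-wise relevance
propagation needs direct access to every weight matrix, and the networks
support locking all bias terms to exactly zero (which makes relevance
conservation exact and the rectifier network positively homogeneous).
Training is Adam on squared error with optional inverted dropout on hidden
units and early stopping on a chronological tail of the training split; model
selection elsewhere optimizes mean absolute error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.tree import DecisionTreeRegressor

from .features import PERSON_VARS

FAMILIES = ("baseline", "elastic_net", "tree", "random_forest", "gbt", "mlp", "rnn")


@dataclass
class TrainedModel:
    """Uniform wrapper: family tag, scope, fitted predictor, feature names."""

    family: str
    scope: str  # "nomothetic" or "ideographic:<person_id>"
    predictor: Any
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        """Continuous stress predictions for a sample frame."""
        if self.family == "baseline":
            return self.predictor.predict(samples["person_id"].to_numpy())
        X = samples[self.feature_names].to_numpy(float)
        return np.asarray(self.predictor.predict(X)).ravel()

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.family == "baseline":
            raise TypeError("baseline predictions require person ids")
        return np.asarray(self.predictor.predict(np.asarray(X, float))).ravel()

    def importances(self) -> Optional[np.ndarray]:
        """Per-feature importance where the family defines one."""
        if self.family == "elastic_net":
            return np.abs(np.asarray(self.predictor.coef_).ravel())
        if self.family in ("tree", "random_forest", "gbt"):
            return np.asarray(self.predictor.feature_importances_)
        return None


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the feature matrix")


def _xy(train: pd.DataFrame, feature_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = train[list(feature_names)].to_numpy(float)
    y = train["y"].to_numpy(float)
    _check_finite(X)
    return X, y


# ---------------------------------------------------------------------------
# baseline and scikit-learn families
# ---------------------------------------------------------------------------


class MedianPredictor:
    """Predicts each person's training-set median rating, for every input."""

    def __init__(self, medians: dict[str, float], default: float):
        self.medians = dict(medians)
        self.default = float(default)

    def predict(self, person_ids) -> np.ndarray:
        return np.array([self.medians.get(p, self.default) for p in person_ids])


def train_baseline(train: pd.DataFrame, scope: str = "nomothetic") -> TrainedModel:
    if len(train) == 0:
        raise ValueError("baseline model needs at least one training sample")
    medians = {
        pid: float(sub["y"].median())
        for pid, sub in train.groupby("person_id", sort=True)
    }
    return TrainedModel(
        family="baseline",
        scope=scope,
        predictor=MedianPredictor(medians, default=float(train["y"].median())),
        feature_names=[],
        metadata={"n_train": len(train)},
    )


def train_elastic_net(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    alpha: float = 0.01,
    l1_ratio: float = 0.5,
    scope: str = "nomothetic",
) -> TrainedModel:
    X, y = _xy(train, feature_names)
    if alpha == 0:
        est = LinearRegression().fit(X, y)
    else:
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000).fit(X, y)
    return TrainedModel(
        family="elastic_net",
        scope=scope,
        predictor=est,
        feature_names=list(feature_names),
        metadata={"alpha": alpha, "l1_ratio": l1_ratio, "n_train": len(train)},
    )


def train_tree(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    max_depth: Optional[int] = 3,
    min_samples_leaf: int = 5,
    seed: int = 0,
    scope: str = "nomothetic",
) -> TrainedModel:
    X, y = _xy(train, feature_names)
    if len(train) < 2 * min_samples_leaf and np.ptp(y) > 0:
        # still fit; with fewer samples the tree degenerates toward a stump
        pass
    est = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    ).fit(X, y)
    return TrainedModel(
        family="tree",
        scope=scope,
        predictor=est,
        feature_names=list(feature_names),
        metadata={
            "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
            "seed": seed,
            "n_train": len(train),
        },
    )


def train_ensemble(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    family: str,
    n_estimators: int = 100,
    max_depth: Optional[int] = 3,
    min_samples_leaf: int = 5,
    learning_rate: float = 0.1,
    max_features: Optional[Any] = None,
    bootstrap: bool = True,
    seed: int = 0,
    scope: str = "nomothetic",
) -> TrainedModel:
    """Random forest (bagging + feature subsampling) or gradient boosting
    (stagewise residual fitting with shrinkage)."""
    X, y = _xy(train, feature_names)
    if family == "random_forest":
        est = RandomForestRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            max_features=max_features if max_features is not None else 1.0,
            bootstrap=bootstrap,
            random_state=seed,
        )
    elif family == "gbt":
        est = GradientBoostingRegressor(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=seed,
        )
    else:
        raise ValueError(f"family must be 'random_forest' or 'gbt', got {family!r}")
    est.fit(X, y)
    return TrainedModel(
        family=family,
        scope=scope,
        predictor=est,
        feature_names=list(feature_names),
        metadata={"n_estimators": n_estimators, "seed": seed, "n_train": len(train)},
    )


# ---------------------------------------------------------------------------
# explicit-weight neural networks
# ---------------------------------------------------------------------------


class DivergenceError(RuntimeError):
    """Raised when network training produces non-finite loss."""


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class LayerStack:
    """Dense feed-forward network: rectifier hidden layers, identity output.

    Weights are plain numpy matrices, exposed for relevance propagation.
    With ``bias_mode='locked_zero'`` every bias is pinned to exactly 0 during
    initialization and training.
    """

    def __init__(self, weights, biases, bias_mode: str = "locked_zero"):
        self.weights = [np.asarray(w, float) for w in weights]
        self.biases = [np.asarray(b, float) for b in biases]
        self.bias_mode = bias_mode
        if bias_mode == "locked_zero":
            for b in self.biases:
                b[...] = 0.0

    @classmethod
    def init(cls, sizes: Sequence[int], bias_mode: str, rng: np.random.Generator):
        weights, biases = [], []
        for din, dout in zip(sizes[:-1], sizes[1:]):
            weights.append(rng.normal(0.0, math.sqrt(2.0 / din), (din, dout)))
            biases.append(np.zeros(dout))
        return cls(weights, biases, bias_mode)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; element 0 is the input, last is the output."""
        acts = [np.asarray(X, float)]
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            acts.append(z if l == self.n_layers - 1 else np.maximum(z, 0.0))
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.forward(X)[-1].ravel()


def _fit_layerstack(
    net: LayerStack,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    lr: float,
    epochs: int,
    batch_size: int,
    dropout_rate: float,
    val_fraction: float,
    patience: int,
) -> None:
    n = len(X)
    n_val = int(val_fraction * n) if n >= 20 else 0
    X_tr, y_tr = (X[:-n_val], y[:-n_val]) if n_val else (X, y)
    X_val, y_val = (X[-n_val:], y[-n_val:]) if n_val else (None, None)
    params = list(net.weights) + ([] if net.bias_mode == "locked_zero" else list(net.biases))
    opt = _Adam(params, lr)
    best = (np.inf, None)
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(len(X_tr))
        for s in range(0, len(X_tr), batch_size):
            idx = order[s:s + batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            # forward with dropout masks on hidden activations
            acts = [xb]
            masks = []
            for l, (W, b) in enumerate(zip(net.weights, net.biases)):
                z = acts[-1] @ W + b
                if l == net.n_layers - 1:
                    acts.append(z)
                else:
                    a = np.maximum(z, 0.0)
                    if dropout_rate > 0:
                        m = (rng.random(a.shape) >= dropout_rate) / (1 - dropout_rate)
                        a = a * m
                        masks.append(m)
                    else:
                        masks.append(None)
                    acts.append(a)
            pred = acts[-1].ravel()
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise DivergenceError("training loss became non-finite")
            delta = (2.0 / len(xb)) * err[:, None]
            w_grads: list[np.ndarray] = [None] * net.n_layers
            b_grads: list[np.ndarray] = [None] * net.n_layers
            for l in range(net.n_layers - 1, -1, -1):
                w_grads[l] = acts[l].T @ delta
                b_grads[l] = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ net.weights[l].T
                    if masks[l - 1] is not None:
                        delta = delta * masks[l - 1]
                    delta = delta * (acts[l] > 0)
            grads = list(w_grads) + ([] if net.bias_mode == "locked_zero" else list(b_grads))
            opt.step(params, grads)
        if X_val is not None:
            val_mae = float(np.mean(np.abs(net.predict(X_val) - y_val)))
            if val_mae < best[0] - 1e-6:
                best = (val_mae, [w.copy() for w in net.weights]
                        + [b.copy() for b in net.biases])
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if best[1] is not None:
        k = net.n_layers
        for i in range(k):
            net.weights[i][...] = best[1][i]
            net.biases[i][...] = best[1][k + i]


def train_mlp(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    hidden: Sequence[int] = (32,),
    dropout_rate: float = 0.2,
    bias_mode: str = "locked_zero",
    seed: int = 0,
    lr: float = 0.01,
    epochs: int = 300,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    patience: int = 25,
    scope: str = "nomothetic",
) -> TrainedModel:
    """Feed-forward network trained by mini-batch Adam on squared error.

    Dropout applies to hidden units during training only.  Early stopping
    monitors MAE on the chronological tail of the training rows (the input
    frame is assumed chronologically ordered per person).
    """
    X, y = _xy(train, feature_names)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    net = LayerStack.init([X.shape[1], *hidden, 1], bias_mode, rng)
    _fit_layerstack(
        net, X, y, rng, lr, epochs, batch_size, dropout_rate, val_fraction, patience
    )
    return TrainedModel(
        family="mlp",
        scope=scope,
        predictor=net,
        feature_names=list(feature_names),
        metadata={
            "hidden": tuple(hidden),
            "dropout_rate": dropout_rate,
            "bias_mode": bias_mode,
            "seed": seed,
            "n_train": len(train),
        },
    )


# ---------------------------------------------------------------------------
# recurrent network
# ---------------------------------------------------------------------------


def sequence_layout(feature_names: Sequence[str]) -> dict:
    """Partition a flat feature vector into per-lag steps plus statics.

    Steps run oldest to newest over the history lags (3, 2, 1), each carrying
    every variable observed at that lag (stress, weather, activity).  Lag-0
    weather, day-of-week indicators, and person covariates are static inputs
    concatenated with the final hidden state.
    """
    names = list(feature_names)
    lags = sorted(
        {int(n.rsplit("_lag", 1)[1]) for n in names if "_lag" in n and not n.endswith("_lag0")},
        reverse=True,
    )
    bases = sorted({n.rsplit("_lag", 1)[0] for n in names if n.endswith("_lag1")})
    step_indices = []
    for k in lags:
        cols = [f"{b}_lag{k}" for b in bases]
        if not all(c in names for c in cols):
            raise ValueError(f"incomplete lag-{k} feature block for RNN layout")
        step_indices.append([names.index(c) for c in cols])
    used = {i for step in step_indices for i in step}
    static_indices = [i for i in range(len(names)) if i not in used]
    return {
        "lags": lags,
        "step_bases": bases,
        "step_indices": step_indices,
        "static_indices": static_indices,
    }


class RecurrentNet:
    """Vanilla rectifier RNN over the lag-day sequence, with static covariates.

    h_t = relu(Wx x_t + Wh h_{t-1} (+ b)), unrolled oldest-to-newest over the
    lag steps; the final hidden state is concatenated with the static inputs
    and mapped linearly to the output.  Exposes an epsilon-rule relevance
    backward pass through the unrolled graph.
    """

    def __init__(self, Wx, Wh, Wout, bh, bout, layout: dict, bias_mode="locked_zero"):
        self.Wx = np.asarray(Wx, float)
        self.Wh = np.asarray(Wh, float)
        self.Wout = np.asarray(Wout, float)  # (hidden + n_static, 1)
        self.bh = np.asarray(bh, float)
        self.bout = np.asarray(bout, float)
        self.layout = layout
        self.bias_mode = bias_mode
        if bias_mode == "locked_zero":
            self.bh[...] = 0.0
            self.bout[...] = 0.0

    @classmethod
    def init(cls, layout: dict, hidden_size: int, bias_mode: str, rng: np.random.Generator):
        d_step = len(layout["step_bases"])
        d_stat = len(layout["static_indices"])
        Wx = rng.normal(0.0, math.sqrt(2.0 / d_step), (d_step, hidden_size))
        Wh = rng.normal(0.0, math.sqrt(1.0 / hidden_size), (hidden_size, hidden_size))
        Wout = rng.normal(0.0, math.sqrt(1.0 / (hidden_size + d_stat)),
                          (hidden_size + d_stat, 1))
        return cls(Wx, Wh, Wout, np.zeros(hidden_size), np.zeros(1), layout, bias_mode)

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        steps = np.stack([X[:, idx] for idx in self.layout["step_indices"]], axis=1)
        static = X[:, self.layout["static_indices"]]
        return steps, static  # (n, T, d_step), (n, d_static)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
        X = np.atleast_2d(np.asarray(X, float))
        steps, static = self._split(X)
        n, T, _ = steps.shape
        h = np.zeros((n, self.Wh.shape[0]))
        hs = []
        for t in range(T):
            h = np.maximum(steps[:, t] @ self.Wx + h @ self.Wh + self.bh, 0.0)
            hs.append(h)
        concat = np.concatenate([h, static], axis=1)
        out = concat @ self.Wout + self.bout
        return out.ravel(), hs, static

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    # -- relevance ----------------------------------------------------------

    def relevance(self, x: np.ndarray, epsilon: float = 1e-9) -> tuple[np.ndarray, float]:
        """Epsilon-rule relevance of each flat input feature for one sample."""
        x = np.asarray(x, float).ravel()
        steps, static = self._split(x[None, :])
        steps, static = steps[0], static[0]
        T = steps.shape[0]
        hs = []
        h = np.zeros(self.Wh.shape[0])
        for t in range(T):
            h = np.maximum(steps[t] @ self.Wx + h @ self.Wh + self.bh, 0.0)
            hs.append(h)
        concat = np.concatenate([hs[-1], static])
        output = float((concat @ self.Wout + self.bout)[0])

        def _denom(z):
            if epsilon == 0 and np.any(z == 0):
                raise ZeroDivisionError("zero pre-activation with epsilon=0")
            return z + epsilon * np.where(z >= 0, 1.0, -1.0)

        relevances = np.zeros_like(x)
        # output layer: distribute over [h_T, static]
        z = concat * self.Wout[:, 0]
        R_concat = z / _denom(z.sum() + float(self.bout[0])) * output
        nh = self.Wh.shape[0]
        R_h = R_concat[:nh]
        relevances[self.layout["static_indices"]] += R_concat[nh:]
        # back through time
        for t in range(T - 1, -1, -1):
            h_prev = hs[t - 1] if t > 0 else np.zeros(nh)
            zx = steps[t][:, None] * self.Wx          # (d_step, hidden)
            zh = h_prev[:, None] * self.Wh            # (hidden, hidden)
            zj = zx.sum(axis=0) + zh.sum(axis=0) + self.bh
            share = R_h / _denom(zj)
            relevances[self.layout["step_indices"][t]] += zx @ share
            R_h = zh @ share
        return relevances, output


def _fit_rnn(
    net: RecurrentNet,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    lr: float,
    epochs: int,
    batch_size: int,
    dropout_rate: float,
    val_fraction: float,
    patience: int,
) -> None:
    n = len(X)
    n_val = int(val_fraction * n) if n >= 20 else 0
    X_tr, y_tr = (X[:-n_val], y[:-n_val]) if n_val else (X, y)
    X_val, y_val = (X[-n_val:], y[-n_val:]) if n_val else (None, None)
    free_bias = net.bias_mode != "locked_zero"
    params = [net.Wx, net.Wh, net.Wout] + ([net.bh, net.bout] if free_bias else [])
    opt = _Adam(params, lr)
    best = (np.inf, None)
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(len(X_tr))
        for s in range(0, len(X_tr), batch_size):
            idx = order[s:s + batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            steps, static = net._split(xb)
            m, T, _ = steps.shape
            nh = net.Wh.shape[0]
            hs, zs = [], []
            h = np.zeros((m, nh))
            for t in range(T):
                z = steps[:, t] @ net.Wx + h @ net.Wh + net.bh
                h = np.maximum(z, 0.0)
                zs.append(z)
                hs.append(h)
            h_out = hs[-1]
            if dropout_rate > 0:
                mask = (rng.random(h_out.shape) >= dropout_rate) / (1 - dropout_rate)
                h_out = h_out * mask
            else:
                mask = None
            concat = np.concatenate([h_out, static], axis=1)
            pred = (concat @ net.Wout + net.bout).ravel()
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise DivergenceError("training loss became non-finite")
            delta = (2.0 / m) * err[:, None]
            gWout = concat.T @ delta
            gbout = delta.sum(axis=0)
            dh = delta @ net.Wout[:nh].T
            if mask is not None:
                dh = dh * mask
            gWx = np.zeros_like(net.Wx)
            gWh = np.zeros_like(net.Wh)
            gbh = np.zeros_like(net.bh)
            for t in range(T - 1, -1, -1):
                dz = dh * (zs[t] > 0)
                gWx += steps[:, t].T @ dz
                gbh += dz.sum(axis=0)
                if t > 0:
                    gWh += hs[t - 1].T @ dz
                    dh = dz @ net.Wh.T
            grads = [gWx, gWh, gWout] + ([gbh, gbout] if free_bias else [])
            for g in grads:  # clip to keep BPTT stable
                np.clip(g, -5.0, 5.0, out=g)
            opt.step(params, grads)
        if X_val is not None:
            val_mae = float(np.mean(np.abs(net.predict(X_val) - y_val)))
            if val_mae < best[0] - 1e-6:
                best = (val_mae, [p.copy() for p in params])
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if best[1] is not None:
        for p, bp in zip(params, best[1]):
            p[...] = bp


def train_rnn(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    hidden_size: int = 16,
    dropout_rate: float = 0.2,
    bias_mode: str = "locked_zero",
    seed: int = 0,
    lr: float = 0.01,
    epochs: int = 300,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    patience: int = 25,
    scope: str = "nomothetic",
) -> TrainedModel:
    """Recurrent network unrolled over the lag-day steps.

    The chosen input layout (which variables are sequence steps vs statics) is
    recorded in the model metadata.
    """
    X, y = _xy(train, feature_names)
    layout = sequence_layout(feature_names)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    net = RecurrentNet.init(layout, hidden_size, bias_mode, rng)
    _fit_rnn(net, X, y, rng, lr, epochs, batch_size, dropout_rate, val_fraction, patience)
    return TrainedModel(
        family="rnn",
        scope=scope,
        predictor=net,
        feature_names=list(feature_names),
        metadata={
            "hidden_size": hidden_size,
            "dropout_rate": dropout_rate,
            "bias_mode": bias_mode,
            "seed": seed,
            "layout": {k: v for k, v in layout.items() if k != "step_indices"},
            "n_train": len(train),
        },
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


def expand_grid(grid: dict[str, Sequence]) -> list[dict]:
    """All combinations of a parameter grid, in the given key/value order.

    Callers list values simplest/most-regularized first so that the
    tie-breaking rule (earliest combination wins) prefers them.
    """
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    trainer: Callable[..., TrainedModel],
    grid: dict[str, Sequence] | list[dict],
    train: pd.DataFrame,
    k: int = 3,
    **fixed,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over a grid with k-fold chronological-block CV.

    The training rows are sorted by date and cut into k contiguous blocks;
    each block is held out once while the remainder trains.  Selection
    minimizes mean held-out MAE; ties go to the earliest grid point (grids are
    ordered simplest-first).  Returns the winning parameters and the full CV
    table (one row per grid point per fold).
    """
    combos = expand_grid(grid) if isinstance(grid, dict) else list(grid)
    if not combos:
        raise ValueError("empty hyperparameter grid")
    ordered = train.sort_values(["target_date", "person_id"]).reset_index(drop=True)
    n = len(ordered)
    bounds = [round(i * n / k) for i in range(k + 1)]
    folds = [ordered.iloc[bounds[i]:bounds[i + 1]] for i in range(k)]
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"cannot form {k} non-empty chronological folds from {n} samples")
    records = []
    for ci, combo in enumerate(combos):
        for fi in range(k):
            fit_df = pd.concat([folds[j] for j in range(k) if j != fi], ignore_index=True)
            model = trainer(fit_df, **combo, **fixed)
            pred = model.predict(folds[fi])
            mae = float(np.mean(np.abs(pred - folds[fi]["y"].to_numpy(float))))
            records.append({"combo_index": ci, "fold": fi, "mae": mae, **combo})
    table = pd.DataFrame(records)
    means = table.groupby("combo_index")["mae"].mean()
    best_index = int(means.index[np.argmin(means.to_numpy())])
    return combos[best_index], table
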