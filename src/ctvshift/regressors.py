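"""The five regression architectures mapping features to one shift component.

Separate models are trained for the SI and AP directions.  Architectures:

* ``br-ann``, ``lm-ann``, ``scg-ann`` -- single-hidden-layer networks
  (4-10 hidden nodes) trained by Bayesian-regularized LM, plain LM and
  scaled conjugate gradient respectively (see :mod:`ctvshift.ann`);
* ``svr`` -- epsilon-insensitive support vector regression with an RBF
  kernel and C set to IQR(targets)/1.349, the robust estimate of the
  target scale;
* ``rf`` -- a regression forest with bootstrap sampling, random feature
  subsets of size ceil(p/3) at each split, and a minimum of 5 samples per
  leaf.

Inputs are z-scored on the training data for the ANNs and SVR (targets
too for the ANNs); the forest operates on raw features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR as _SkSVR

from . import ann

ARCHITECTURES = ("br-ann", "lm-ann", "scg-ann", "svr", "rf")
HIDDEN_NODE_GRID = (4, 5, 6, 7, 8, 9, 10)
EPSILON_GRID = (0.01, 0.05, 0.1, 0.3, 0.5, 1.0)
N_TREES_GRID = (10, 30, 50, 70, 100, 150)

DEFAULT_HYPERPARAMETERS = {
    "br-ann": {"hidden_nodes": 4},
    "lm-ann": {"hidden_nodes": 4},
    "scg-ann": {"hidden_nodes": 4},
    "svr": {"epsilon": 0.1},
    "rf": {"n_trees": 100},
}


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    direction: str  # 'si' or 'ap'
    n_features: int
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.direction not in ("si", "ap"):
            raise ValueError("direction must be 'si' or 'ap'")
        if not 1 <= self.n_features <= 9:
            raise ValueError("n_features must be in 1..9")


class TrainedRegressor:
    """A fitted model plus the standardization statistics it was fitted with."""

    def __init__(self, spec: ModelSpec, x_mean: np.ndarray, x_scale: np.ndarray,
                 y_mean: float, y_scale: float,
                 predict_std: Callable[[np.ndarray], np.ndarray],
                 state: object = None, training_sse: float | None = None):
        self.spec = spec
        self.x_mean = x_mean
        self.x_scale = x_scale
        self.y_mean = y_mean
        self.y_scale = y_scale
        self._predict_std = predict_std
        self.state = state
        self.training_sse = training_sse

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted shift component in mm for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.x_mean):
            raise ValueError(
                f"expected {len(self.x_mean)} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        Xs = (X - self.x_mean) / self.x_scale
        out = self._predict_std(Xs) * self.y_scale + self.y_mean
        return np.asarray(out, dtype=float).ravel()


def _standardize(X: np.ndarray, y: np.ndarray, scale_y: bool):
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    if scale_y:
        y_mean, y_scale = float(y.mean()), float(y.std())
        if y_scale < 1e-12:
            y_scale = 1.0
    else:
        y_mean, y_scale = 0.0, 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    return Xs, ys, x_mean, x_scale, y_mean, y_scale


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    return X, y


def _train_ann(fit_fn, X, y, hidden_nodes: int, seed: int, spec: ModelSpec):
    X, y = _check_xy(X, y)
    Xs, ys, *stats = _standardize(X, y, scale_y=True)
    net = fit_fn(Xs, ys, hidden_nodes, seed)
    return TrainedRegressor(spec, *stats, predict_std=net.forward, state=net,
                            training_sse=net.sse_history[-1] if net.sse_history else None)


def train_lm_ann(X, y, hidden_nodes: int = 4, seed: int = 0,
                 direction: str = "si", n_features: int | None = None) -> TrainedRegressor:
    spec = ModelSpec("lm-ann", direction, n_features or np.atleast_2d(X).shape[1],
                     {"hidden_nodes": hidden_nodes}, seed)
    return _train_ann(ann.fit_lm, X, y, hidden_nodes, seed, spec)


def train_br_ann(X, y, hidden_nodes: int = 4, seed: int = 0,
                 direction: str = "si", n_features: int | None = None) -> TrainedRegressor:
    spec = ModelSpec("br-ann", direction, n_features or np.atleast_2d(X).shape[1],
                     {"hidden_nodes": hidden_nodes}, seed)
    return _train_ann(ann.fit_br, X, y, hidden_nodes, seed, spec)


def train_scg_ann(X, y, hidden_nodes: int = 4, seed: int = 0,
                  direction: str = "si", n_features: int | None = None) -> TrainedRegressor:
    spec = ModelSpec("scg-ann", direction, n_features or np.atleast_2d(X).shape[1],
                     {"hidden_nodes": hidden_nodes}, seed)
    return _train_ann(ann.fit_scg, X, y, hidden_nodes, seed, spec)


def svr_regularization(y: np.ndarray) -> float:
    """C = IQR(y)/1.349, the toolbox default tying the box constraint to the target scale."""
    q1, q3 = np.percentile(np.asarray(y, dtype=float), [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        warnings.warn("target IQR is zero; falling back to C = 1", stacklevel=2)
        return 1.0
    return float(iqr / 1.349)


def train_svr(X, y, epsilon: float = 0.1, direction: str = "si",
              n_features: int | None = None, seed: int = 0) -> TrainedRegressor:
    """RBF-kernel epsilon-SVR; C from the target IQR, gamma = 1/p on z-scored inputs."""
    X, y = _check_xy(X, y)
    spec = ModelSpec("svr", direction, n_features or X.shape[1],
                     {"epsilon": epsilon}, seed)
    Xs, ys, *stats = _standardize(X, y, scale_y=False)
    C = svr_regularization(y)
    model = _SkSVR(kernel="rbf", C=C, epsilon=epsilon,
                   gamma=1.0 / X.shape[1], tol=1e-6)
    model.fit(Xs, ys)
    resid = ys - model.predict(Xs)
    reg = TrainedRegressor(spec, *stats, predict_std=model.predict, state=model,
                           training_sse=float(resid @ resid))
    reg.C = C  # type: ignore[attr-defined]
    return reg


def train_rf(X, y, n_trees: int = 100, seed: int = 0, direction: str = "si",
             n_features: int | None = None) -> TrainedRegressor:
    """Regression forest: bootstrap per tree, ceil(p/3) features per split, min leaf 5."""
    X, y = _check_xy(X, y)
    if X.shape[0] < 5:
        raise ValueError("random forest needs at least 5 samples (min leaf size)")
    spec = ModelSpec("rf", direction, n_features or X.shape[1],
                     {"n_trees": n_trees}, seed)
    p = X.shape[1]
    model = RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=5,
        max_features=max(1, math.ceil(p / 3)),
        bootstrap=True, random_state=seed)
    model.fit(X, y)
    resid = y - model.predict(X)
    # identity standardization: trees are invariant to monotone rescaling
    return TrainedRegressor(spec, np.zeros(p), np.ones(p), 0.0, 1.0,
                            predict_std=model.predict, state=model,
                            training_sse=float(resid @ resid))


_TRAINERS = {
    "br-ann": lambda X, y, hp, seed, d: train_br_ann(X, y, hp.get("hidden_nodes", 4), seed, d),
    "lm-ann": lambda X, y, hp, seed, d: train_lm_ann(X, y, hp.get("hidden_nodes", 4), seed, d),
    "scg-ann": lambda X, y, hp, seed, d: train_scg_ann(X, y, hp.get("hidden_nodes", 4), seed, d),
    "svr": lambda X, y, hp, seed, d: train_svr(X, y, hp.get("epsilon", 0.1), d, seed=seed),
    "rf": lambda X, y, hp, seed, d: train_rf(X, y, hp.get("n_trees", 100), seed, d),
}


def train(X, y, architecture: str, hyperparameters: dict | None = None,
          seed: int = 0, direction: str = "si") -> TrainedRegressor:
    """Train one architecture on (X, y); dispatches to the dedicated trainers."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    hp = dict(DEFAULT_HYPERPARAMETERS[architecture])
    hp.update(hyperparameters or {})
    return _TRAINERS[architecture](X, y, hp, seed, direction)


def predict(model: TrainedRegressor, X) -> np.ndarray:
    return model.predict(X)


def _grid_key(architecture: str) -> tuple[str, Sequence]:
    return {
        "br-ann": ("hidden_nodes", HIDDEN_NODE_GRID),
        "lm-ann": ("hidden_nodes", HIDDEN_NODE_GRID),
        "scg-ann": ("hidden_nodes", HIDDEN_NODE_GRID),
        "svr": ("epsilon", EPSILON_GRID),
        "rf": ("n_trees", N_TREES_GRID),
    }[architecture]


def select_hyperparameters(X, y, architecture: str,
                           grid: Iterable | None = None, seed: int = 0,
                           direction: str = "si") -> tuple[str, float]:
    """Pick the grid value minimizing mean absolute *training* error.

    Mirrors a one-parameter-at-a-time search over the stated grids
    (hidden nodes 4-10, SVR epsilon, forest size); ties go to the smallest
    grid value.  Returns (hyperparameter name, best value).
    """
    key, default_grid = _grid_key(architecture)
    values = sorted(grid) if grid is not None else list(default_grid)
    if not values:
        raise ValueError("hyperparameter grid is empty")
    X, y = _check_xy(X, y)
    best_value, best_err = None, np.inf
    for value in values:
        model = train(X, y, architecture, {key: value}, seed=seed, direction=direction)
        err = float(np.mean(np.abs(y - model.predict(X))))
        if err < best_err - 1e-12:
            best_value, best_err = value, err
    return key, best_value
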