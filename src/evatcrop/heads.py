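"""Per-combination neural regression heads.

Each head is a one-hidden-layer perceptron mapping an interim vector
(length 3^k) to a scalar ET0 estimate, trained by the limited-memory
BFGS quasi-Newton optimizer on a squared-error loss (scikit-learn's
``MLPRegressor`` with ``solver="lbfgs"`` does the fitting). Hidden size
and activation are chosen by seeded k-fold grid search with deterministic
tie-breaking. Fitted weights are extracted into plain arrays so that
prediction is an explicit forward pass, which makes persisted models
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

#: activation order used for tie-breaking in the grid search
ACTIVATIONS: tuple[str, ...] = ("identity", "logistic", "tanh", "relu")

#: default hidden-size grid, 2..16 inclusive
DEFAULT_HIDDEN_GRID: tuple[int, ...] = tuple(range(2, 17))


@dataclass(frozen=True)
class HeadSpec:
    """Architecture of one head."""

    input_dim: int
    hidden_units: int
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


@dataclass(frozen=True)
class TrainingConfig:
    """L-BFGS training controls.

    ``max_iterations`` bounds the quasi-Newton iterations, ``tolerance``
    is the relative loss/gradient stopping threshold, and ``seed`` fixes
    the small random initial weights, making training fully reproducible.
    """

    max_iterations: int = 400
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class TrainedHead:
    """Fitted head: spec plus layer weights and training metadata.

    ``w1`` is (input_dim, hidden_units), ``b1`` (hidden_units,),
    ``w2`` (hidden_units,), ``b2`` scalar.
    """

    spec: HeadSpec
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    seed: int
    n_iterations: int
    final_loss: float


def _activation_fn(name: str):
    return {
        "identity": lambda z: z,
        "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
        "tanh": np.tanh,
        "relu": lambda z: np.maximum(z, 0.0),
    }[name]


def _as_matrix(X, input_dim: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != input_dim:
        raise ValueError(f"expected (n, {input_dim}) design matrix, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the design matrix")
    return X


def fit_head(X, y, spec: HeadSpec, cfg: TrainingConfig | None = None) -> TrainedHead:
    """Train one head on interim vectors ``X`` against targets ``y``.

    L-BFGS iterates w_{k+1} = w_k + η_k d_k with search direction
    d_k = −H_k ∇E(w_k), where H_k is the limited-memory inverse-Hessian
    estimate and η_k the line-search step; the squared-error loss is
    non-increasing across accepted steps. Same seed and data give
    bitwise-identical weights.
    """
    cfg = cfg or TrainingConfig()
    X = _as_matrix(X, spec.input_dim)
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("y must be one target per row of X")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite targets")
    if X.shape[0] < spec.hidden_units:
        raise ValueError("need at least as many samples as hidden units")
    est = MLPRegressor(
        hidden_layer_sizes=(spec.hidden_units,),
        activation=spec.activation,
        solver="lbfgs",
        max_iter=cfg.max_iterations,
        tol=cfg.tolerance,
        random_state=cfg.seed,
    )
    import warnings
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return TrainedHead(
        spec=spec,
        w1=est.coefs_[0].copy(),
        b1=est.intercepts_[0].copy(),
        w2=est.coefs_[1].ravel().copy(),
        b2=float(np.ravel(est.intercepts_[1])[0]),
        seed=cfg.seed,
        n_iterations=int(est.n_iter_),
        final_loss=float(est.loss_),
    )


def predict_head(head: TrainedHead, X) -> np.ndarray:
    """Deterministic forward pass: activation(X·w1 + b1)·w2 + b2."""
    X = _as_matrix(X, head.spec.input_dim)
    hidden = _activation_fn(head.spec.activation)(X @ head.w1 + head.b1)
    return hidden @ head.w2 + head.b2


def grid_search_head(
    X,
    y,
    input_dim: int,
    hidden_grid: Sequence[int] = DEFAULT_HIDDEN_GRID,
    activations: Sequence[str] = ACTIVATIONS,
    cfg: TrainingConfig | None = None,
    n_folds: int = 5,
) -> HeadSpec:
    """Select hidden size and activation by k-fold cross-validated MSE.

    Folds are contiguous and unshuffled (the data are chronological).
    Ties break toward fewer hidden units, then toward the earlier entry
    of :data:`ACTIVATIONS`.
    """
    if not hidden_grid:
        raise ValueError("hidden_grid must be non-empty")
    if n_folds < 2:
        raise ValueError("need at least two folds")
    cfg = cfg or TrainingConfig()
    X = _as_matrix(X, input_dim)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < n_folds:
        raise ValueError("fewer samples than folds")
    folds = list(KFold(n_splits=n_folds, shuffle=False).split(X))

    best: tuple[float, int, int] | None = None  # (score, hidden, activation index)
    best_spec: HeadSpec | None = None
    for act_i, act in enumerate(activations):
        for hidden in hidden_grid:
            spec = HeadSpec(input_dim=input_dim, hidden_units=hidden, activation=act)
            errs = []
            for tr, va in folds:
                head = fit_head(X[tr], y[tr], spec, cfg)
                resid = predict_head(head, X[va]) - y[va]
                errs.append(float(np.mean(resid ** 2)))
            key = (float(np.mean(errs)), hidden, ACTIVATIONS.index(act))
            if best is None or key < best:
                best, best_spec = key, spec
    assert best_spec is not None
    return best_spec
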