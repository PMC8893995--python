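"""One-hidden-layer feed-forward network for predictor-subset validation.

The network maps min-max-scaled predictors through ``H`` hidden nodes with
activation ``g`` to a single linear output node:

    yhat(x) = sum_j w_j * g(sum_i v_ji * scale(x_i) + E1_j) + E2

Subsets of candidate predictors are ranked by held-out mean squared error:
the subset whose trained network generalises best is taken as the
validated variable set.  Training is deterministic full-batch gradient
descent under a seed; the indicator columns of a categorical variable are
always kept or dropped together.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ConfigurationError, DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MLPConfig",
    "MLPModel",
    "SubsetScore",
    "split_train_test",
    "train_mlp",
    "predict",
    "mse",
    "select_variables",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few rows for the requested operation."""


@dataclass(frozen=True)
class MLPConfig:
    """Training configuration.

    ``hidden_nodes`` is the hidden-layer width H (default 2);
    ``train_fraction`` the share of rows used for training (default 0.7,
    i.e. a 70:30 train/test split); ``learning_rate`` applies to scaled
    data and is halved automatically whenever a step increases the loss.
    """

    hidden_nodes: int = 2
    activation: str = "logistic"
    train_fraction: float = 0.7
    max_iterations: int = 2000
    learning_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie strictly in (0, 1)")
        if self.hidden_nodes < 1:
            raise ConfigurationError("hidden_nodes must be >= 1")
        if self.activation not in ("logistic", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.max_iterations < 1 or self.learning_rate <= 0:
            raise ConfigurationError("max_iterations and learning_rate must be positive")


def _activation(name: str):
    if name == "logistic":
        return (lambda z: 1.0 / (1.0 + np.exp(-z))), (lambda a: a * (1.0 - a))
    return np.tanh, (lambda a: 1.0 - a * a)


@dataclass(frozen=True)
class MLPModel:
    """Fitted network weights plus the scaling used at fit time.

    ``input_scaling`` holds one (min, max) pair per input column;
    ``output_scaling`` the (min, max) of the training response, inverted
    at prediction so reported errors are on the raw response scale.  The
    default output scaling (0, 1) is the identity.
    """

    input_columns: tuple[str, ...]
    input_to_hidden_weights: np.ndarray = field(repr=False)  # H x N
    hidden_bias: np.ndarray = field(repr=False)  # H
    hidden_to_output_weights: np.ndarray = field(repr=False)  # H
    output_bias: float = 0.0
    activation: str = "logistic"
    input_scaling: tuple[tuple[float, float], ...] = ()
    output_scaling: tuple[float, float] = (0.0, 1.0)
    response_name: str = "y"
    converged: bool = True

    def __post_init__(self) -> None:
        h, n = self.input_to_hidden_weights.shape
        if len(self.hidden_bias) != h or len(self.hidden_to_output_weights) != h:
            raise ConfigurationError("hidden-layer dimensions inconsistent")
        if n != len(self.input_columns) or len(self.input_scaling) != n:
            raise ConfigurationError("input dimensions inconsistent with scaling/columns")


def _scale_inputs(model: MLPModel, X: np.ndarray) -> np.ndarray:
    lo = np.array([s[0] for s in model.input_scaling])
    hi = np.array([s[1] for s in model.input_scaling])
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def predict(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Forward pass for raw (unscaled) input rows; returns raw-scale predictions."""
    g, _ = _activation(model.activation)
    Xs = _scale_inputs(model, np.atleast_2d(X))
    hidden = g(Xs @ model.input_to_hidden_weights.T + model.hidden_bias)
    out = hidden @ model.hidden_to_output_weights + model.output_bias
    lo, hi = model.output_scaling
    return out * (hi - lo) + lo


def split_train_test(
    matrix: DesignMatrix, train_fraction: float, seed: int
) -> tuple[DesignMatrix, DesignMatrix]:
    """Disjoint random row partition: round(f*m) rows to train, rest to test.

    The train count is clamped so both partitions are non-empty.
    Deterministic under ``seed``.
    """
    m = matrix.n_rows
    if m < 2:
        raise InsufficientDataError("need at least 2 rows to split")
    n_train = int(round(train_fraction * m))
    n_train = min(max(n_train, 1), m - 1)
    perm = np.random.default_rng(seed).permutation(m)
    return matrix.take_rows(np.sort(perm[:n_train])), matrix.take_rows(np.sort(perm[n_train:]))


def _design_inputs(matrix: DesignMatrix) -> tuple[tuple[str, ...], np.ndarray]:
    # the network has its own biases, so the intercept column is not an input
    cols = tuple(c for c in matrix.columns if c != "Intercept")
    idx = [matrix.column_index(c) for c in cols]
    return cols, matrix.X[:, idx]


def train_mlp(train: DesignMatrix, config: MLPConfig) -> MLPModel:
    """Fit the network to ``train`` by full-batch gradient descent.

    Inputs are min-max scaled to [0, 1] with train-set ranges (stored on
    the model); the response is likewise scaled internally and unscaled at
    prediction.  The learning rate is halved whenever a step would
    increase the training loss, which makes descent monotone.  If the
    final loss does not fall below the initialisation loss a convergence
    warning is issued and the model is still returned.
    """
    cols, X = _design_inputs(train)
    y = train.y
    if len(y) == 0 or not cols:
        raise InsufficientDataError("training set is empty or has no predictors")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    ylo, yhi = float(y.min()), float(y.max())
    yspan = (yhi - ylo) if yhi > ylo else 1.0
    ys = (y - ylo) / yspan

    H, N = config.hidden_nodes, len(cols)
    rng = np.random.default_rng(config.seed)
    V = rng.uniform(-0.5, 0.5, size=(H, N))
    b1 = rng.uniform(-0.5, 0.5, size=H)
    w = rng.uniform(-0.5, 0.5, size=H)
    b2 = float(rng.uniform(-0.5, 0.5))

    g, gprime = _activation(config.activation)
    n = len(ys)

    def loss(V, b1, w, b2):
        a = g(Xs @ V.T + b1)
        p = a @ w + b2
        return float(np.mean((p - ys) ** 2)), a, p

    lr = config.learning_rate
    cur, a, p = loss(V, b1, w, b2)
    initial = cur
    for _ in range(config.max_iterations):
        dLdp = 2.0 * (p - ys) / n
        grad_w = a.T @ dLdp
        grad_b2 = dLdp.sum()
        delta = np.outer(dLdp, w) * gprime(a)
        grad_V = delta.T @ Xs
        grad_b1 = delta.sum(axis=0)

        V_new = V - lr * grad_V
        b1_new = b1 - lr * grad_b1
        w_new = w - lr * grad_w
        b2_new = b2 - lr * grad_b2
        new, a_new, p_new = loss(V_new, b1_new, w_new, b2_new)
        if new <= cur:
            V, b1, w, b2 = V_new, b1_new, w_new, b2_new
            cur, a, p = new, a_new, p_new
        else:
            lr *= 0.5
            if lr < 1e-12:
                break

    converged = cur < initial
    if not converged:
        warnings.warn("MLP training failed to reduce the training MSE; model returned as-is")
    return MLPModel(
        input_columns=cols,
        input_to_hidden_weights=V,
        hidden_bias=b1,
        hidden_to_output_weights=w,
        output_bias=b2,
        activation=config.activation,
        input_scaling=tuple((float(a_), float(b_)) for a_, b_ in zip(lo, hi)),
        output_scaling=(ylo, ylo + yspan),
        response_name=train.response_name,
        converged=converged,
    )


def mse(model: MLPModel, data: DesignMatrix) -> float:
    """Mean squared prediction error on the raw response scale."""
    cols, X = _design_inputs(data)
    if cols != model.input_columns:
        raise ConfigurationError(
            f"data columns {cols} do not match model inputs {model.input_columns}"
        )
    resid = data.y - predict(model, X)
    return float(np.mean(resid**2))


@dataclass(frozen=True)
class SubsetScore:
    """Held-out performance of one predictor subset."""

    subset: tuple[str, ...]
    test_mse: float
    train_mse: float

    def __post_init__(self) -> None:
        if not self.subset:
            raise ConfigurationError("subset must be non-empty")


def select_variables(
    matrix: DesignMatrix,
    candidates: list[str] | tuple[str, ...],
    config: MLPConfig,
    max_subsets: int = 2**12,
) -> list[SubsetScore]:
    """Rank every non-empty subset of candidate predictor blocks by test MSE.

    A categorical variable's indicator columns move as one block.  Each
    subset's network is trained on the same seeded train/test partition.
    Ties are broken by smaller subset, then lexicographic label order.
    """
    if not candidates:
        raise ConfigurationError("at least one candidate predictor required")
    for c in candidates:
        if c not in matrix.groups:
            raise ConfigurationError(f"unknown predictor block {c!r}")
    n_subsets = 2 ** len(candidates) - 1
    if n_subsets > max_subsets:
        raise ConfigurationError(
            f"{n_subsets} subsets exceed the cap of {max_subsets}; "
            "reduce candidates or use a forward-selection strategy"
        )

    scores: list[SubsetScore] = []
    for r in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            sub = matrix.subset(list(combo))
            train, test = split_train_test(sub, config.train_fraction, config.seed)
            model = train_mlp(train, config)
            scores.append(
                SubsetScore(
                    subset=combo,
                    test_mse=mse(model, test),
                    train_mse=mse(model, train),
                )
            )
    scores.sort(key=lambda s: (s.test_mse, len(s.subset), s.subset))
    logger.info("scored %d predictor subsets; best: %s", len(scores), scores[0].subset)
    return scores
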