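"""Three-layer feed-forward regression network.

The network maps a vector of lagged series values to a one-step-ahead
forecast.  Hidden units compute H_j = tanh(sum_i w_ij x_i - b_j); the
single linear output unit computes sum_j v_j H_j - b_out.  Thresholds are
*subtracted*, matching the classical perceptron convention (this is an
equivalent reparameterization of the usual +bias form).

Training refines PSO-seeded (or randomly initialized) weights by resilient
backpropagation (Rprop): each parameter keeps its own step size, grown
when the gradient keeps its sign and shrunk when it flips, which makes the
method insensitive to the raw gradient magnitude.  Plain gradient descent
with momentum is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, NumericFailureError

__all__ = [
    "MLPParameters",
    "TrainConfig",
    "Normalizer",
    "hidden_node_count",
    "normalize",
    "denormalize",
    "lag_embed",
    "init_params",
    "forward",
    "predict",
    "mse_loss",
    "gradient",
    "train",
]


@dataclass(frozen=True)
class MLPParameters:
    """Weights and thresholds of a (n_i, n_h, 1) network.

    input_hidden_weights has shape (n_h, n_i): row j holds the fan-in of
    hidden unit j.  All thresholds enter with a minus sign in the
    activations.
    """

    input_hidden_weights: np.ndarray
    hidden_thresholds: np.ndarray
    hidden_output_weights: np.ndarray
    output_threshold: float

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.input_hidden_weights, dtype=float))
        bh = np.asarray(self.hidden_thresholds, dtype=float).ravel()
        v = np.asarray(self.hidden_output_weights, dtype=float).ravel()
        if w.shape[0] != bh.size or w.shape[0] != v.size:
            raise InvalidInputError(
                f"inconsistent shapes: weights {w.shape}, hidden thresholds "
                f"{bh.size}, output weights {v.size}"
            )
        if not (
            np.all(np.isfinite(w))
            and np.all(np.isfinite(bh))
            and np.all(np.isfinite(v))
            and np.isfinite(self.output_threshold)
        ):
            raise InvalidInputError("parameters must be finite")
        object.__setattr__(self, "input_hidden_weights", w)
        object.__setattr__(self, "hidden_thresholds", bh)
        object.__setattr__(self, "hidden_output_weights", v)
        object.__setattr__(self, "output_threshold", float(self.output_threshold))

    @property
    def n_inputs(self) -> int:
        return self.input_hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.input_hidden_weights.shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to (input->hidden row-major, hidden thresholds,
        hidden->output weights, output threshold)."""
        return np.concatenate(
            [
                self.input_hidden_weights.ravel(),
                self.hidden_thresholds,
                self.hidden_output_weights,
                [self.output_threshold],
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_i: int, n_h: int) -> "MLPParameters":
        vec = np.asarray(vec, dtype=float).ravel()
        expected = n_i * n_h + 2 * n_h + 1
        if vec.size != expected:
            raise InvalidInputError(
                f"vector length {vec.size} != {expected} for a ({n_i}, {n_h}, 1) net"
            )
        k = n_i * n_h
        return cls(
            input_hidden_weights=vec[:k].reshape(n_h, n_i),
            hidden_thresholds=vec[k : k + n_h],
            hidden_output_weights=vec[k + n_h : k + 2 * n_h],
            output_threshold=float(vec[-1]),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Refinement-training settings (defaults follow common practice for
    small regression networks: 1000 epochs, goal MSE 0.01 on the
    normalized scale, learning rate 0.15, gradient floor 1e-6)."""

    max_epochs: int = 1000
    goal_mse: float = 0.01
    learning_rate: float = 0.15
    min_gradient: float = 1e-6
    momentum: float = 0.9
    algorithm: Literal["rprop", "gdm"] = "rprop"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.goal_mse, self.learning_rate, self.min_gradient) <= 0:
            raise InvalidInputError("training settings must be positive")
        if self.algorithm not in ("rprop", "gdm"):
            raise InvalidInputError(f"unknown training algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class Normalizer:
    """Min-max scaling of a series onto [-1, 1] and back."""

    observed_min: float
    observed_max: float

    def __post_init__(self) -> None:
        if not self.observed_max > self.observed_min:
            raise DegenerateInputError("min-max scaling needs observed_max > observed_min")


def hidden_node_count(n1: int, n3: int, m: int) -> int:
    """Empirical hidden-layer size n2 = n1 + n3 + m with m in [1, 10]."""
    if not 1 <= m <= 10:
        raise InvalidInputError(f"m must be in [1, 10], got {m}")
    if n1 < 1 or n3 < 1:
        raise InvalidInputError("layer sizes must be >= 1")
    return n1 + n3 + m


def normalize(series: np.ndarray) -> tuple[np.ndarray, Normalizer]:
    """Scale a series onto [-1, 1]: min maps to -1, max to +1."""
    x = np.asarray(series, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    norm = Normalizer(lo, hi)  # raises on constant input
    return 2.0 * (x - lo) / (hi - lo) - 1.0, norm


def denormalize(scaled: np.ndarray, norm: Normalizer) -> np.ndarray:
    """Exact inverse of :func:`normalize`."""
    s = np.asarray(scaled, dtype=float)
    lo, hi = norm.observed_min, norm.observed_max
    return (s + 1.0) * (hi - lo) / 2.0 + lo


def lag_embed(series: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Autoregressive design matrix: row k = (x[k], ..., x[k+n_lags-1]),
    target k = x[k+n_lags]."""
    x = np.asarray(series, dtype=float)
    if n_lags < 1:
        raise InvalidInputError("n_lags must be >= 1")
    if x.size <= n_lags:
        raise InvalidInputError(f"series of length {x.size} too short for {n_lags} lags")
    n_pairs = x.size - n_lags
    inputs = np.stack([x[k : k + n_lags] for k in range(n_pairs)])
    targets = x[n_lags:]
    return inputs, targets.copy()


def init_params(n_i: int, n_h: int, seed: int = 0) -> MLPParameters:
    """Uniform [-1, 1] initialization (the PSO search box), seeded."""
    rng = np.random.default_rng(seed)
    vec = rng.uniform(-1.0, 1.0, size=n_i * n_h + 2 * n_h + 1)
    return MLPParameters.from_vector(vec, n_i, n_h)


def _hidden(params: MLPParameters, X: np.ndarray) -> np.ndarray:
    return np.tanh(X @ params.input_hidden_weights.T - params.hidden_thresholds)


def predict(params: MLPParameters, inputs: np.ndarray) -> np.ndarray:
    """Batch forward pass: one prediction per row of ``inputs``."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != params.n_inputs:
        raise InvalidInputError(
            f"input width {X.shape[1]} != network input size {params.n_inputs}"
        )
    H = _hidden(params, X)
    return H @ params.hidden_output_weights - params.output_threshold


def forward(params: MLPParameters, input_vector: np.ndarray) -> float:
    """Single forward pass: scalar forecast for one lag vector."""
    x = np.asarray(input_vector, dtype=float).ravel()
    return float(predict(params, x[None, :])[0])


def mse_loss(params: MLPParameters, inputs: np.ndarray, targets: np.ndarray) -> float:
    e = predict(params, inputs) - np.asarray(targets, dtype=float).ravel()
    return float(np.mean(e * e))


def gradient(
    params: MLPParameters, inputs: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the MSE loss, flattened in to_vector() layout."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = y.size
    H = _hidden(params, X)  # (n, n_h)
    pred = H @ params.hidden_output_weights - params.output_threshold
    d_pred = 2.0 * (pred - y) / n  # (n,)
    g_v = H.T @ d_pred  # hidden->output weights
    g_bout = -float(np.sum(d_pred))  # output threshold (enters negated)
    d_H = np.outer(d_pred, params.hidden_output_weights)  # (n, n_h)
    d_z = d_H * (1.0 - H * H)  # tanh'
    g_W = d_z.T @ X  # (n_h, n_i)
    g_bh = -d_z.sum(axis=0)  # hidden thresholds (negated)
    return np.concatenate([g_W.ravel(), g_bh, g_v, [g_bout]])


def train(
    params: MLPParameters,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[MLPParameters, np.ndarray]:
    """Refine network parameters on normalized data.

    Runs Rprop (default) or gradient descent with momentum until the epoch
    MSE reaches ``goal_mse``, the gradient max-norm falls below
    ``min_gradient``, or ``max_epochs`` elapse.  Returns the best
    parameters seen (so the final loss never exceeds the initial loss) and
    the per-epoch MSE history, whose first entry is the loss of the given
    parameters before any update.
    """
    cfg = cfg or TrainConfig()
    n_i, n_h = params.n_inputs, params.n_hidden
    w = params.to_vector()
    history = [mse_loss(params, inputs, targets)]
    if history[0] <= cfg.goal_mse:
        return params, np.asarray(history)

    best_w, best_loss = w.copy(), history[0]
    # Rprop state: per-parameter step sizes and previous gradient signs.
    step = np.full(w.size, 0.07)
    grad_prev = np.zeros(w.size)
    velocity = np.zeros(w.size)  # momentum buffer for gdm

    for epoch in range(cfg.max_epochs):
        g = gradient(MLPParameters.from_vector(w, n_i, n_h), inputs, targets)
        if not np.all(np.isfinite(g)):
            raise NumericFailureError(f"non-finite gradient at epoch {epoch}")
        if np.max(np.abs(g)) <= cfg.min_gradient:
            break
        if cfg.algorithm == "rprop":
            sign_change = g * grad_prev
            step = np.where(sign_change > 0, np.minimum(step * 1.2, 50.0), step)
            step = np.where(sign_change < 0, np.maximum(step * 0.5, 1e-6), step)
            g_eff = np.where(sign_change < 0, 0.0, g)  # skip update on sign flip
            w = w - np.sign(g_eff) * step
            grad_prev = g_eff
        else:
            velocity = cfg.momentum * velocity - cfg.learning_rate * g
            w = w + velocity
        loss = mse_loss(MLPParameters.from_vector(w, n_i, n_h), inputs, targets)
        if not np.isfinite(loss):
            raise NumericFailureError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
        if loss < best_loss:
            best_loss, best_w = loss, w.copy()
        if loss <= cfg.goal_mse:
            break
    return MLPParameters.from_vector(best_w, n_i, n_h), np.asarray(history)
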