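"""Small backpropagation network mapping sEMG features to a joint angle.

Architecture: 15 inputs -> 6 hidden units with the ``tansig`` activation
(2/(1+e^(-2n)) - 1, identical to tanh) -> 1 linear (``purelin``) output.
Training is full-batch gradient descent on the mean-squared error with a
fixed learning rate, stopping at a goal MSE or an epoch budget
(defaults 0.001 / 10,000 at rate 0.01).

Inputs and targets are z-scored with statistics from the training set, so
the hidden units operate in their sensitive range and the goal MSE is on the
standardized target scale; predictions are mapped back to degrees and
clamped to the active angle convention's range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .features import FeatureMatrix
from .signal_core import (
    AngleConvention,
    AngleTrajectory,
    clamp_to_convention,
)

__all__ = [
    "tansig",
    "purelin",
    "NetworkSpec",
    "TrainingSpec",
    "TrainedModel",
    "init_network",
    "train",
    "predict",
    "save_model",
    "load_model",
]


def tansig(n: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2n)) - 1 == tanh(n)."""
    return np.tanh(n)


def purelin(n: np.ndarray) -> np.ndarray:
    """Identity (linear) transfer function."""
    return n


@dataclass(frozen=True)
class NetworkSpec:
    n_input: int = 15
    n_hidden: int = 6
    n_output: int = 1

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be >= 1")


@dataclass(frozen=True)
class TrainingSpec:
    """Gradient-descent hyperparameters.

    ``goal_mse`` is measured on standardized targets (variance 1), so 0.001
    corresponds to explaining 99.9% of the target variance.
    """

    max_epochs: int = 10_000
    learning_rate: float = 0.01
    goal_mse: float = 0.001
    seed: int = 0
    momentum: float = 0.0
    standardize_targets: bool = True

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not self.goal_mse > 0:
            raise ValueError("goal_mse must be positive")


@dataclass(frozen=True)
class TrainedModel:
    """Network weights plus the standardization statistics that define it.

    ``w1`` has shape (n_hidden, n_input), ``w2`` (n_output, n_hidden); biases
    are column vectors.  ``history`` holds the per-epoch training MSE.
    """

    spec: NetworkSpec
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float = 0.0
    y_std: float = 1.0
    seed: int = 0
    history: tuple[float, ...] = field(default_factory=tuple)


def init_network(spec: NetworkSpec | None = None, seed: int = 0) -> TrainedModel:
    """Initialize weights uniformly in [-1/sqrt(fan_in), +1/sqrt(fan_in)]."""
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(spec.n_input)
    lim2 = 1.0 / np.sqrt(spec.n_hidden)
    return TrainedModel(
        spec=spec,
        w1=rng.uniform(-lim1, lim1, (spec.n_hidden, spec.n_input)),
        b1=rng.uniform(-lim1, lim1, (spec.n_hidden, 1)),
        w2=rng.uniform(-lim2, lim2, (spec.n_output, spec.n_hidden)),
        b2=rng.uniform(-lim2, lim2, (spec.n_output, 1)),
        x_mean=np.zeros(spec.n_input),
        x_std=np.ones(spec.n_input),
        seed=seed,
    )


def _as_matrix(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _forward(model: TrainedModel, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass on standardized inputs; returns (hidden, output)."""
    hidden = tansig(xs @ model.w1.T + model.b1.T)
    out = hidden @ model.w2.T + model.b2.T
    return hidden, out


def _loss_and_grads(
    model: TrainedModel, xs: np.ndarray, ys: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE and its analytic gradients w.r.t. all weights and biases.

    Backpropagation of L = mean over samples and outputs of (pred - y)^2.
    Exposed for gradient verification.
    """
    n = xs.shape[0]
    hidden, out = _forward(model, xs)
    err = out - ys
    mse = float(np.mean(err**2))
    scale = 2.0 / err.size
    d_out = scale * err  # dL/d(out)
    g_w2 = d_out.T @ hidden
    g_b2 = d_out.sum(axis=0, keepdims=True).T
    d_hidden = (d_out @ model.w2) * (1.0 - hidden**2)  # tanh'
    g_w1 = d_hidden.T @ xs
    g_b1 = d_hidden.sum(axis=0, keepdims=True).T
    return mse, {"w1": g_w1, "b1": g_b1, "w2": g_w2, "b2": g_b2}


def train(
    model: TrainedModel,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    tspec: TrainingSpec | None = None,
) -> TrainedModel:
    """Full-batch gradient-descent backpropagation on the MSE.

    Standardization statistics are computed from the given training data
    only.  Training stops when the epoch MSE reaches ``goal_mse`` or the
    epoch budget is spent; the per-epoch MSE is recorded in ``history``.
    Bit-reproducible for identical data and seed.
    """
    tspec = tspec or TrainingSpec()
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if Xm.ndim != 2 or Xm.shape[0] != y.size:
        raise ValueError("X rows and y must be aligned")
    if Xm.shape[0] == 0:
        raise ValueError("cannot train on an empty training set")
    if Xm.shape[1] != model.spec.n_input:
        raise ValueError(
            f"X has {Xm.shape[1]} features but the network expects "
            f"{model.spec.n_input}"
        )
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise ValueError("training data contain NaN or Inf")

    x_mean = Xm.mean(axis=0)
    x_std = Xm.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    if tspec.standardize_targets:
        y_mean = float(y.mean())
        y_std = float(y.std()) or 1.0
    else:
        y_mean, y_std = 0.0, 1.0
    xs = (Xm - x_mean) / x_std
    ys = ((y - y_mean) / y_std).reshape(-1, 1)

    params = {
        "w1": model.w1.copy(),
        "b1": model.b1.copy(),
        "w2": model.w2.copy(),
        "b2": model.b2.copy(),
    }
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    current = replace(model, x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std)
    history: list[float] = []
    for _ in range(tspec.max_epochs):
        current = replace(current, **params)
        mse, grads = _loss_and_grads(current, xs, ys)
        history.append(mse)
        if mse <= tspec.goal_mse:
            break
        for k in params:
            velocity[k] = tspec.momentum * velocity[k] - tspec.learning_rate * grads[k]
            params[k] = params[k] + velocity[k]
    current = replace(current, **params, history=tuple(history))
    return current


def predict(
    model: TrainedModel,
    X: FeatureMatrix | np.ndarray,
    convention: AngleConvention = AngleConvention.PALM_UP_ZERO,
) -> AngleTrajectory | np.ndarray:
    """Map feature vectors to angles (degrees).

    Given a :class:`FeatureMatrix` the result is an :class:`AngleTrajectory`
    timestamped at the window centers, de-standardized and clamped to the
    convention's range; a bare array yields the clamped angle array.
    """
    Xm = _as_matrix(X)
    if Xm.ndim != 2 or Xm.shape[1] != model.spec.n_input:
        raise ValueError(
            f"X must have {model.spec.n_input} feature columns, got shape {Xm.shape}"
        )
    xs = (Xm - model.x_mean) / model.x_std
    _, out = _forward(model, xs)
    angles = clamp_to_convention(
        out.reshape(-1) * model.y_std + model.y_mean, convention
    )
    if isinstance(X, FeatureMatrix):
        return AngleTrajectory(X.window_centers, angles, convention)
    return angles


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist weights, biases, standardization stats, spec, and seed."""
    np.savez_compressed(
        Path(path),
        layer_sizes=np.array(
            [model.spec.n_input, model.spec.n_hidden, model.spec.n_output]
        ),
        w1=model.w1,
        b1=model.b1,
        w2=model.w2,
        b2=model.b2,
        x_mean=model.x_mean,
        x_std=model.x_std,
        y_mean=model.y_mean,
        y_std=model.y_std,
        seed=model.seed,
        history=np.array(model.history),
    )


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as data:
        n_in, n_hid, n_out = (int(v) for v in data["layer_sizes"])
        return TrainedModel(
            spec=NetworkSpec(n_in, n_hid, n_out),
            w1=data["w1"],
            b1=data["b1"],
            w2=data["w2"],
            b2=data["b2"],
            x_mean=data["x_mean"],
            x_std=data["x_std"],
            y_mean=float(data["y_mean"]),
            y_std=float(data["y_std"]),
            seed=int(data["seed"]),
            history=tuple(float(v) for v in data["history"]),
        )
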