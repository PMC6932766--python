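"""From-scratch 3-layer back-propagation network.

Logistic-sigmoid (optionally ReLU-hidden) feed-forward network trained by
per-pattern (online) gradient descent with momentum and bias weights, using
the root-mean-square output error as the stopping criterion.

Conventions
-----------
* Weight matrices carry the bias as their last row: ``W_ih`` has shape
  ``(n_input + 1, n_hidden)`` and ``W_ho`` has shape
  ``(n_hidden + 1, n_output)``.  With ``use_bias=False`` the bias rows are
  pinned at zero and never updated.
* Targets are one-hot over the output neurons; predictions are the argmax
  of the output activations, ties broken toward the lower index.
* One "epoch" is a full pass over all patterns in a seeded shuffled order
  with an update after each pattern; the epoch RMS is evaluated afterwards
  with the weights frozen:  ``rms = sqrt(sum((t - o)^2) / (P * K))``.
* Weights are initialized uniformly in [-0.5, 0.5] from ``cfg.seed``.

The ReLU option applies to the hidden layer only; the output layer always
uses the logistic sigmoid so that outputs stay in (0, 1) and the RMS
criterion remains meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .exceptions import ShapeError, ValidationError

try:  # optional JIT acceleration of the online training loop
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "TrainResult",
    "init_state",
    "forward",
    "backprop_step",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("logistic_sigmoid", "relu")


@dataclass
class NetworkConfig:
    """Training hyperparameters (defaults follow the study's common setup)."""

    n_input: int = 400
    n_hidden: int = 45
    n_output: int = 2
    learning_rate: float = 0.00079
    momentum: float = 0.90
    min_rms: float = 0.003
    activation: str = "logistic_sigmoid"
    use_bias: bool = True
    max_epochs: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValidationError("layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValidationError("momentum must lie in [0, 1)")
        if self.min_rms <= 0:
            raise ValidationError("min_rms must be > 0")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(
                f"activation must be one of {_ACTIVATIONS}, got {self.activation!r}"
            )
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass
class NetworkState:
    """Weights (bias rows last) plus the momentum buffers."""

    w_ih: np.ndarray
    w_ho: np.ndarray
    prev_delta_ih: np.ndarray
    prev_delta_ho: np.ndarray
    activation: str = "logistic_sigmoid"
    use_bias: bool = True

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.w_ih.copy(),
            self.w_ho.copy(),
            self.prev_delta_ih.copy(),
            self.prev_delta_ho.copy(),
            activation=self.activation,
            use_bias=self.use_bias,
        )

    @property
    def n_input(self) -> int:
        return self.w_ih.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    @property
    def n_output(self) -> int:
        return self.w_ho.shape[1]


@dataclass
class TrainResult:
    state: NetworkState
    epochs_run: int
    final_rms: float
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def init_state(cfg: NetworkConfig) -> NetworkState:
    """Random initial weights in [-0.5, 0.5] (seeded); zero momentum buffers."""
    rng = np.random.default_rng(cfg.seed)
    w_ih = rng.uniform(-0.5, 0.5, size=(cfg.n_input + 1, cfg.n_hidden))
    w_ho = rng.uniform(-0.5, 0.5, size=(cfg.n_hidden + 1, cfg.n_output))
    if not cfg.use_bias:
        w_ih[-1, :] = 0.0
        w_ho[-1, :] = 0.0
    return NetworkState(
        w_ih,
        w_ho,
        np.zeros_like(w_ih),
        np.zeros_like(w_ho),
        activation=cfg.activation,
        use_bias=cfg.use_bias,
    )


def _hidden_act(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    return expit(z)


def _forward_full(state: NetworkState, x: np.ndarray):
    """Returns (hidden pre-activation, hidden, output). x may be 1D or 2D."""
    h_pre = x @ state.w_ih[:-1] + state.w_ih[-1]
    h = _hidden_act(h_pre, state.activation)
    o = expit(h @ state.w_ho[:-1] + state.w_ho[-1])
    return h_pre, h, o


def _check_input(state: NetworkState, x) -> np.ndarray:
    x = np.asarray(getattr(x, "values", x), dtype=np.float64).ravel()
    if x.size != state.n_input:
        raise ShapeError(
            f"input length {x.size} != network n_input {state.n_input}"
        )
    return x


def forward(state: NetworkState, x) -> np.ndarray:
    """Output activations for one pattern (each in (0, 1))."""
    return _forward_full(state, _check_input(state, x))[2]


def predict(state: NetworkState, x) -> int:
    """Argmax decision rule; ties go to the lower class index."""
    return int(np.argmax(forward(state, x)))


def _step_inplace(
    state: NetworkState, x: np.ndarray, target: np.ndarray, cfg: NetworkConfig
) -> None:
    """One online delta-rule update with momentum, mutating ``state``."""
    h_pre, h, o = _forward_full(state, x)
    delta_o = (target - o) * o * (1.0 - o)
    if state.activation == "relu":
        dh = np.where(h_pre > 0.0, 1.0, 0.0)
    else:
        dh = h * (1.0 - h)
    delta_h = (state.w_ho[:-1] @ delta_o) * dh

    eta, alpha = cfg.learning_rate, cfg.momentum
    d_ho = state.prev_delta_ho
    d_ho *= alpha
    d_ho[:-1] += eta * np.outer(h, delta_o)
    d_ih = state.prev_delta_ih
    d_ih *= alpha
    d_ih[:-1] += eta * np.outer(x, delta_h)
    if state.use_bias:
        d_ho[-1] += eta * delta_o
        d_ih[-1] += eta * delta_h
    state.w_ho += d_ho
    state.w_ih += d_ih


def backprop_step(
    state: NetworkState, x, target: Sequence[float], cfg: NetworkConfig
) -> NetworkState:
    """One online update for pattern ``x`` with one-hot ``target``; returns a new state."""
    x = _check_input(state, x)
    target = np.asarray(target, dtype=np.float64).ravel()
    if target.size != state.n_output:
        raise ShapeError(
            f"target length {target.size} != network n_output {state.n_output}"
        )
    out = state.copy()
    _step_inplace(out, x, target, cfg)
    return out


def _epoch_python(X, T, w_ih, w_ho, d_ih, d_ho, order, eta, alpha, relu, use_bias):
    """Reference per-pattern epoch; same math as the JIT kernel."""
    for idx in order:
        x = X[idx]
        h_pre = x @ w_ih[:-1] + w_ih[-1]
        h = np.maximum(h_pre, 0.0) if relu else expit(h_pre)
        o = expit(h @ w_ho[:-1] + w_ho[-1])
        delta_o = (T[idx] - o) * o * (1.0 - o)
        dh = np.where(h_pre > 0.0, 1.0, 0.0) if relu else h * (1.0 - h)
        delta_h = (w_ho[:-1] @ delta_o) * dh
        d_ho *= alpha
        d_ho[:-1] += eta * np.outer(h, delta_o)
        d_ih *= alpha
        d_ih[:-1] += eta * np.outer(x, delta_h)
        if use_bias:
            d_ho[-1] += eta * delta_o
            d_ih[-1] += eta * delta_h
        w_ho += d_ho
        w_ih += d_ih


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _epoch_jit(X, T, w_ih, w_ho, d_ih, d_ho, order, eta, alpha, relu, use_bias):
        n_in = w_ih.shape[0] - 1
        n_h = w_ih.shape[1]
        n_out = w_ho.shape[1]
        h_pre = np.empty(n_h)
        h = np.empty(n_h)
        delta_o = np.empty(n_out)
        delta_h = np.empty(n_h)
        for p in range(order.shape[0]):
            idx = order[p]
            for j in range(n_h):
                h_pre[j] = w_ih[n_in, j]
            for i in range(n_in):
                xi = X[idx, i]
                if xi != 0.0:
                    for j in range(n_h):
                        h_pre[j] += xi * w_ih[i, j]
            for j in range(n_h):
                if relu:
                    h[j] = h_pre[j] if h_pre[j] > 0.0 else 0.0
                else:
                    h[j] = 1.0 / (1.0 + math.exp(-h_pre[j]))
            for k in range(n_out):
                s = w_ho[n_h, k]
                for j in range(n_h):
                    s += h[j] * w_ho[j, k]
                ok = 1.0 / (1.0 + math.exp(-s))
                delta_o[k] = (T[idx, k] - ok) * ok * (1.0 - ok)
            for j in range(n_h):
                s = 0.0
                for k in range(n_out):
                    s += w_ho[j, k] * delta_o[k]
                if relu:
                    delta_h[j] = s if h_pre[j] > 0.0 else 0.0
                else:
                    delta_h[j] = s * h[j] * (1.0 - h[j])
            for j in range(n_h + 1):
                hj = 1.0 if j == n_h else h[j]
                for k in range(n_out):
                    grad = eta * delta_o[k] * hj
                    if j == n_h and not use_bias:
                        grad = 0.0
                    d = alpha * d_ho[j, k] + grad
                    d_ho[j, k] = d
                    w_ho[j, k] += d
            for i in range(n_in + 1):
                xi = 1.0 if i == n_in else X[idx, i]
                for j in range(n_h):
                    grad = eta * delta_h[j] * xi
                    if i == n_in and not use_bias:
                        grad = 0.0
                    d = alpha * d_ih[i, j] + grad
                    d_ih[i, j] = d
                    w_ih[i, j] += d


def _batch_rms(state: NetworkState, X: np.ndarray, T: np.ndarray) -> float:
    _, _, O = _forward_full(state, X)
    return float(np.sqrt(np.mean((T - O) ** 2)))


def train(
    data: Sequence[tuple], cfg: NetworkConfig, record_history: bool = True
) -> TrainResult:
    """Train on ``(feature_vector, class_index)`` pairs until RMS <= min_rms.

    Patterns are visited once per epoch in a seeded shuffled order with an
    update after each; the epoch-end RMS (weights frozen) drives stopping.
    Deterministic given ``(data, cfg.seed)``.
    """
    if len(data) == 0:
        raise ValidationError("empty training set")
    X = np.stack(
        [np.asarray(getattr(x, "values", x), dtype=np.float64).ravel() for x, _ in data]
    )
    labels = np.asarray([int(y) for _, y in data])
    if X.shape[1] != cfg.n_input:
        raise ShapeError(f"feature length {X.shape[1]} != n_input {cfg.n_input}")
    if labels.min() < 0 or labels.max() >= cfg.n_output:
        raise ValidationError("class indices out of range for n_output")
    if len(np.unique(labels)) < cfg.n_output:
        raise ValidationError("need at least one pattern per class")
    T = np.zeros((len(data), cfg.n_output))
    T[np.arange(len(data)), labels] = 1.0

    state = init_state(cfg)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    )
    epoch_fn = _epoch_jit if _HAVE_NUMBA else _epoch_python
    relu = cfg.activation == "relu"
    history: list[float] = []
    rms = _batch_rms(state, X, T)
    epochs = 0
    converged = rms <= cfg.min_rms
    while not converged and epochs < cfg.max_epochs:
        order = shuffle_rng.permutation(len(data))
        epoch_fn(
            X,
            T,
            state.w_ih,
            state.w_ho,
            state.prev_delta_ih,
            state.prev_delta_ho,
            order,
            cfg.learning_rate,
            cfg.momentum,
            relu,
            cfg.use_bias,
        )
        epochs += 1
        rms = _batch_rms(state, X, T)
        if record_history:
            history.append(rms)
        converged = rms <= cfg.min_rms
    return TrainResult(
        state=state,
        epochs_run=epochs,
        final_rms=rms,
        converged=converged,
        rms_history=history,
    )


def save_model(
    result: TrainResult, cfg: NetworkConfig, path: str | Path
) -> None:
    """Serialize weights + config + training provenance to a JSON file."""
    payload = {
        "config": {
            "n_input": cfg.n_input,
            "n_hidden": cfg.n_hidden,
            "n_output": cfg.n_output,
            "learning_rate": cfg.learning_rate,
            "momentum": cfg.momentum,
            "min_rms": cfg.min_rms,
            "activation": cfg.activation,
            "use_bias": cfg.use_bias,
            "max_epochs": cfg.max_epochs,
            "seed": cfg.seed,
        },
        "epochs_run": result.epochs_run,
        "final_rms": result.final_rms,
        "converged": result.converged,
        "w_ih": result.state.w_ih.tolist(),
        "w_ho": result.state.w_ho.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[NetworkState, NetworkConfig]:
    payload = json.loads(Path(path).read_text())
    cfg = NetworkConfig(**payload["config"])
    w_ih = np.asarray(payload["w_ih"], dtype=np.float64)
    w_ho = np.asarray(payload["w_ho"], dtype=np.float64)
    state = NetworkState(
        w_ih,
        w_ho,
        np.zeros_like(w_ih),
        np.zeros_like(w_ho),
        activation=cfg.activation,
        use_bias=cfg.use_bias,
    )
    return state, cfg
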