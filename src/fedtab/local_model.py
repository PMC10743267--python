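"""Client-side feed-forward classifier and its training loop.

The network is a dense multilayer perceptron: an input layer sized to the
selected features, three rectifier hidden layers (64, 32, 16 by default), one
rectifier fully-connected layer (8) and a 2-unit output head whose activations
are normalised into class probabilities.  Training is mini-batch gradient
descent with adaptive-moment (Adam) updates on the sparse categorical
cross-entropy loss, per-epoch seeded shuffling, and early stopping on
validation loss with best-weight restoration.

Everything is plain NumPy: the model is a list of (W, b) arrays, so weight
averaging across federation clients is a literal arithmetic mean.  Each model
also carries z-scoring statistics of its own training split, applied inside
``predict_proba`` — the first, frozen "layer" of the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import ConfigError, FedtabError, FeatureTable

_FORMAT_VERSION = 1
_INIT_SCHEME = "he_normal"


@dataclass(frozen=True)
class NetworkSpec:
    input_dim: int
    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    fc_size: int = 8
    output_units: int = 2
    output_activation: str = "softmax"  # or "sigmoid" (per-unit, row-normalised)

    def __post_init__(self) -> None:
        sizes = (self.input_dim, *self.hidden_sizes, self.fc_size)
        if any(s < 1 for s in sizes):
            raise ConfigError("all layer sizes must be >= 1")
        if self.output_units != 2:
            raise ConfigError("the classifier head is binary: output_units must be 2")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ConfigError("output_activation must be 'softmax' or 'sigmoid'")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, self.fc_size, self.output_units)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 70
    batch_size: int = 32
    patience: int | None = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.patience is not None and self.patience < 0:
            raise ConfigError("patience must be >= 0")


@dataclass
class LocalModel:
    spec: NetworkSpec
    weights: list[tuple[np.ndarray, np.ndarray]]  # [(W, b)] per layer
    trained: bool = False
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None

    def copy(self) -> "LocalModel":
        return LocalModel(
            spec=self.spec,
            weights=[(W.copy(), b.copy()) for W, b in self.weights],
            trained=self.trained,
            input_mean=None if self.input_mean is None else self.input_mean.copy(),
            input_std=None if self.input_std is None else self.input_std.copy(),
        )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def build_model(spec: NetworkSpec, seed: int = 0) -> LocalModel:
    """Initialise weights with the seeded fan-in-scaled (He) scheme."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return LocalModel(spec=spec, weights=weights)


def _forward(model: LocalModel, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Probabilities plus per-layer post-activation cache for backprop."""
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(model.weights):
        z = a @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)  # ReLU hidden/fc layers
        elif model.spec.output_activation == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)
        else:  # per-unit sigmoid, normalised into a probability row
            s = 0.5 * (1.0 + np.tanh(0.5 * z))
            a = s / s.sum(axis=1, keepdims=True)
        acts.append(a)
    return a, acts


def _apply_scaling(model: LocalModel, X: np.ndarray) -> np.ndarray:
    if model.input_mean is not None:
        X = (X - model.input_mean) / model.input_std
    return X


def predict_proba(model: LocalModel, X: np.ndarray) -> np.ndarray:
    """(n, 2) class-probability rows; each row is nonnegative and sums to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise FedtabError(
            f"input arity {X.shape} does not match model input_dim {model.spec.input_dim}"
        )
    probs, _ = _forward(model, _apply_scaling(model, X))
    return probs


def predict(model: LocalModel, X: np.ndarray) -> np.ndarray:
    """Hard labels; probability ties resolve toward class 0 (benign)."""
    p = predict_proba(model, X)
    return np.where(p[:, 1] > p[:, 0], 1, 0)


def _loss_and_grads(model, X, y):
    """Cross-entropy on integer labels + backprop grads for every (W, b)."""
    n = len(X)
    probs, acts = _forward(model, X)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    if model.spec.output_activation == "softmax":
        delta = (probs - onehot) / n  # d loss / d logits
    else:
        # p = s / S with s = sigmoid(z): dL/dz_k = (p_k - 1{k=y}) * (1 - s_k)
        z = acts[-2] @ model.weights[-1][0] + model.weights[-1][1]
        s = 0.5 * (1.0 + np.tanh(0.5 * z))
        delta = (probs - onehot) * (1.0 - s) / n
    grads = [None] * len(model.weights)
    for i in range(len(model.weights) - 1, -1, -1):
        a_prev = acts[i]
        grads[i] = (a_prev.T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ model.weights[i][0].T) * (acts[i] > 0)
    return loss, grads


def _evaluate(model, X, y) -> tuple[float, float]:
    probs, _ = _forward(model, X)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
    acc = float((np.argmax(probs, axis=1) == y).mean())
    return loss, acc


def train_local(
    model: LocalModel,
    train: FeatureTable,
    val: FeatureTable,
    cfg: TrainConfig | None = None,
) -> tuple[LocalModel, TrainingHistory]:
    """Mini-batch Adam training with early stopping on validation loss.

    The model's input-scaling statistics are (re)fit on the training split.
    Training stops once validation loss has not improved for ``cfg.patience``
    consecutive epochs (or after ``cfg.epochs``), and the weights of the best
    validation epoch are restored.
    """
    cfg = cfg or TrainConfig()
    if len(train) == 0:
        raise FedtabError("empty training set")
    if train.n_features != model.spec.input_dim or val.n_features != model.spec.input_dim:
        raise FedtabError("feature arity does not match model input_dim")
    model = model.copy()
    mean = train.features.mean(axis=0)
    std = train.features.std(axis=0)
    model.input_mean = mean
    model.input_std = np.where(std > 0, std, 1.0)
    Xtr = _apply_scaling(model, train.features)
    ytr = train.labels
    Xva = _apply_scaling(model, val.features)
    yva = val.labels

    rng = np.random.default_rng(cfg.seed)
    mom = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    t = 0
    hist = TrainingHistory()
    best_loss, best_weights, best_epoch, stall = np.inf, None, 0, 0

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_losses = []
        for start in range(0, len(Xtr), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, grads = _loss_and_grads(model, Xtr[batch], ytr[batch])
            epoch_losses.append(loss)
            t += 1
            new_weights = []
            for i, (W, b) in enumerate(model.weights):
                gW, gb = grads[i]
                mW = cfg.beta1 * mom[i][0] + (1 - cfg.beta1) * gW
                mb = cfg.beta1 * mom[i][1] + (1 - cfg.beta1) * gb
                vW = cfg.beta2 * vel[i][0] + (1 - cfg.beta2) * gW**2
                vb = cfg.beta2 * vel[i][1] + (1 - cfg.beta2) * gb**2
                mom[i], vel[i] = (mW, mb), (vW, vb)
                mhW = mW / (1 - cfg.beta1**t)
                mhb = mb / (1 - cfg.beta1**t)
                vhW = vW / (1 - cfg.beta2**t)
                vhb = vb / (1 - cfg.beta2**t)
                new_weights.append(
                    (
                        W - cfg.learning_rate * mhW / (np.sqrt(vhW) + cfg.eps),
                        b - cfg.learning_rate * mhb / (np.sqrt(vhb) + cfg.eps),
                    )
                )
            model.weights = new_weights
        _, tr_acc = _evaluate(model, Xtr, ytr)
        va_loss, va_acc = (
            _evaluate(model, Xva, yva) if len(val) else (float("nan"), float("nan"))
        )
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.train_acc.append(tr_acc)
        hist.val_loss.append(va_loss)
        hist.val_acc.append(va_acc)
        hist.stopped_epoch = epoch
        if len(val) and va_loss < best_loss:
            best_loss = va_loss
            best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
        if cfg.patience is not None and len(val) and stall >= cfg.patience:
            break
    if best_weights is not None:
        model.weights = best_weights
        hist.best_epoch = best_epoch
    model.trained = True
    return model, hist


def save_model(model: LocalModel, path: str | Path) -> None:
    """Serialise spec, weights and scaling statistics to a versioned JSON archive."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "init_scheme": _INIT_SCHEME,
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden_sizes": list(model.spec.hidden_sizes),
            "fc_size": model.spec.fc_size,
            "output_units": model.spec.output_units,
            "output_activation": model.spec.output_activation,
        },
        "trained": model.trained,
        "weights": [[W.tolist(), b.tolist()] for W, b in model.weights],
        "input_mean": None if model.input_mean is None else model.input_mean.tolist(),
        "input_std": None if model.input_std is None else model.input_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path, expected_spec: NetworkSpec | None = None) -> LocalModel:
    try:
        payload = json.loads(Path(path).read_text())
        spec = NetworkSpec(
            input_dim=payload["spec"]["input_dim"],
            hidden_sizes=tuple(payload["spec"]["hidden_sizes"]),
            fc_size=payload["spec"]["fc_size"],
            output_units=payload["spec"]["output_units"],
            output_activation=payload["spec"]["output_activation"],
        )
        weights = [
            (np.asarray(W, dtype=float), np.asarray(b, dtype=float))
            for W, b in payload["weights"]
        ]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FedtabError(f"corrupt model archive {path}: {exc}")
    if expected_spec is not None and spec != expected_spec:
        raise FedtabError(f"model spec in {path} does not match the expected spec")
    mean = payload.get("input_mean")
    std = payload.get("input_std")
    return LocalModel(
        spec=spec,
        weights=weights,
        trained=payload.get("trained", False),
        input_mean=None if mean is None else np.asarray(mean, dtype=float),
        input_std=None if std is None else np.asarray(std, dtype=float),
    )
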