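"""Feed-forward classifiers: per-family binary nets and the stacking meta-net.

Architecture (shared by base learners and stacker, which differ only in input
and output width): four fully connected hidden layers of 256, 128, 64 and 32
units, each ReLU-activated and followed by 0.5 dropout during training. The
binary output is a single sigmoid unit trained with binary cross-entropy; the
stacker output is a softmax over the family set trained with multi-class
cross-entropy. Both are optimized with Adam.

The implementation is pure numpy: He-initialized weights, inverted dropout,
mini-batch Adam, early stopping on a held-out validation fold, all driven by a
single PCG64 generator so that a given seed reproduces training bit-for-bit in
single-threaded mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN = (256, 128, 64, 32)
DEFAULT_DROPOUT = 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    """Fully determines a network's architecture for reconstruction."""

    input_dim: int
    output_dim: int = 1
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    dropout: float = DEFAULT_DROPOUT
    activation: str = "relu"
    output: str = "sigmoid"  # "sigmoid" (binary) | "softmax" (stacker)

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.hidden, self.hidden[1:])):
            raise ValueError("hidden widths must be strictly decreasing")
        if self.output not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown output head {self.output!r}")
        if self.output == "sigmoid" and self.output_dim != 1:
            raise ValueError("sigmoid head implies output_dim == 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule. Defaults: Adam(1e-3), batches of 64, early
    stopping on a 10% validation fold.

    Family subsets span two orders of magnitude in size, so the epoch budget
    and patience are floored in *optimizer updates* rather than epochs: a
    32-row subset (one batch per epoch) trains for up to
    ``min_updates`` steps, while large subsets keep the plain
    ``max_epochs``/``patience`` limits. ``input_noise`` is the standard
    deviation of Gaussian jitter added to (standardized) training inputs, a
    data-space regularizer complementing dropout.
    """

    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    min_updates: int = 8000
    patience_updates: int = 2000
    val_fraction: float = 0.1
    input_noise: float = 2.5
    input_noise_mode: str = "fixed"  # "fixed" sigma | "uniform": sigma ~ U(0, input_noise) per row
    seed: int = 0


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class _Net:
    """Weights + forward/backward for the fixed ReLU/dropout architecture."""

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden, spec.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims, dims[1:]):
            if rng is None:
                w = np.zeros((d_in, d_out))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
            self.weights.append(w)
            self.biases.append(np.zeros(d_out))

    def forward(
        self, X: np.ndarray, dropout_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Returns (output probabilities, cache for backprop).

        Dropout is applied only when ``dropout_rng`` is given (training mode);
        inference is deterministic.
        """
        cache = []
        a = X
        n_hidden = len(self.spec.hidden)
        for i in range(n_hidden):
            z = a @ self.weights[i] + self.biases[i]
            h = _relu(z)
            if dropout_rng is not None and self.spec.dropout > 0:
                keep = 1.0 - self.spec.dropout
                mask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            cache.append((a, z, mask))
            a = h
        z_out = a @ self.weights[-1] + self.biases[-1]
        cache.append((a, z_out, None))
        p = _sigmoid(z_out) if self.spec.output == "sigmoid" else _softmax(z_out)
        return p, cache

    def backward(
        self,
        cache: list,
        p: np.ndarray,
        target: np.ndarray,
        weight: np.ndarray | None = None,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of the mean cross-entropy loss w.r.t. all parameters.

        For both sigmoid/BCE and softmax/CE the output-layer error is p - y;
        ``weight`` rescales each sample's contribution (class balancing).
        """
        n = p.shape[0]
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        if weight is None:
            delta = (p - target) / n
        else:
            delta = (p - target) * (weight / weight.sum())[:, None]
        a_in, _, _ = cache[-1]
        grads_w[-1] = a_in.T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for i in range(len(self.spec.hidden) - 1, -1, -1):
            a_prev, z, mask = cache[i]
            delta = delta @ self.weights[i + 1].T
            if mask is not None:
                delta = delta * mask
            delta = delta * (z > 0)
            grads_w[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
        return grads_w, grads_b

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]


def _loss(
    p: np.ndarray,
    target: np.ndarray,
    output: str,
    weight: np.ndarray | None = None,
) -> float:
    """Mean (optionally sample-weighted) cross-entropy."""
    eps = 1e-12
    if output == "sigmoid":
        per_row = -(
            target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps)
        )[:, 0]
    else:
        per_row = -np.log((p * target).sum(axis=1) + eps)
    if weight is None:
        return float(per_row.mean())
    return float((per_row * weight).sum() / weight.sum())


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A trained network plus the metadata needed to reload and audit it."""

    spec: ClassifierSpec
    net: _Net
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def save(self, prefix: str | Path) -> None:
        """Persist as ``<prefix>.json`` (spec + meta) and ``<prefix>.npz`` (weights)."""
        prefix = Path(prefix)
        payload = {"spec": asdict(self.spec), "training_meta": self.training_meta}
        payload["spec"]["hidden"] = list(self.spec.hidden)
        prefix.with_suffix(".json").write_text(json.dumps(payload))
        arrays = {f"w{i}": w for i, w in enumerate(self.net.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.biases)})
        np.savez(prefix.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedModel":
        prefix = Path(prefix)
        payload = json.loads(prefix.with_suffix(".json").read_text())
        payload["spec"]["hidden"] = tuple(payload["spec"]["hidden"])
        spec = ClassifierSpec(**payload["spec"])
        net = _Net(spec, rng=None)
        with np.load(prefix.with_suffix(".npz")) as arrays:
            net.weights = [arrays[f"w{i}"] for i in range(len(net.weights))]
            net.biases = [arrays[f"b{i}"] for i in range(len(net.biases))]
        return cls(spec=spec, net=net, training_meta=payload["training_meta"])


def _fit(
    X: np.ndarray,
    target: np.ndarray,
    spec: ClassifierSpec,
    config: TrainConfig,
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray | None] | None = None,
    sample_weight: np.ndarray | None = None,
) -> TrainedModel:
    """Core mini-batch Adam loop with early stopping.

    ``val_data`` (X_val, t_val, optional per-row weights) overrides the
    internal 10% validation fold; ``sample_weight`` rescales each training
    row's loss contribution (class balancing for the stacker).
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    net = _Net(spec, rng=rng)
    adam = _Adam(net.params(), config.learning_rate)

    n = X.shape[0]
    if val_data is not None:
        X_val, t_val, w_val = val_data
        n_val = len(X_val)
        X_tr, t_tr, w_tr = X, target, sample_weight
        rng.permutation(n)  # keep the stream layout identical either way
    else:
        w_val = None
        n_val = max(1, int(round(config.val_fraction * n))) if n > 4 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        X_tr, t_tr = X[train_idx], target[train_idx]
        X_val, t_val = X[val_idx], target[val_idx]
        w_tr = None if sample_weight is None else sample_weight[train_idx]

    updates_per_epoch = max(1, -(-len(X_tr) // config.batch_size))
    max_epochs = max(config.max_epochs, -(-config.min_updates // updates_per_epoch))
    patience = max(config.patience, -(-config.patience_updates // updates_per_epoch))

    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = 0
    patience_left = patience
    history: list[dict] = []

    for epoch in range(max_epochs):
        perm = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(X_tr), config.batch_size):
            idx = perm[start : start + config.batch_size]
            w_batch = None if w_tr is None else w_tr[idx]
            xb = X_tr[idx]
            if config.input_noise > 0:
                # Gaussian input jitter: with a handful of positives per
                # family the net otherwise memorizes single spurious
                # features; noise forces it onto the redundant motif signal.
                # "uniform" mode draws the jitter scale per row from
                # U(0, input_noise), exposing the net to both crisp and fuzzy
                # inputs (noise-level randomization).
                if config.input_noise_mode == "uniform":
                    sig = rng.uniform(0.0, config.input_noise, size=(len(idx), 1))
                else:
                    sig = config.input_noise
                xb = xb + sig * rng.normal(size=xb.shape)
            p, cache = net.forward(xb, dropout_rng=rng)
            loss = _loss(p, t_tr[idx], spec.output, w_batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check inputs for NaN/inf or lower the learning rate"
                )
            grads_w, grads_b = net.backward(cache, p, t_tr[idx], w_batch)
            adam.step(net.params(), grads_w + grads_b)
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if n_val:
            p_val, _ = net.forward(X_val)
            val_loss = _loss(p_val, t_val, spec.output, w_val)
            record["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = net.copy_params()
                best_epoch = epoch
                patience_left = patience
            else:
                patience_left -= 1
        history.append(record)
        if n_val and patience_left <= 0:
            break

    if n_val:
        net.set_params(best_params)
    meta = {
        "seed": config.seed,
        "epochs_run": len(history),
        "best_epoch": best_epoch if n_val else len(history) - 1,
        "final_train_loss": history[-1]["train_loss"] if history else None,
        "best_val_loss": None if not n_val else best_val,
        "history": history,
    }
    return TrainedModel(spec=spec, net=net, training_meta=meta)


def train_binary(
    X: np.ndarray,
    y: Sequence[int],
    spec: ClassifierSpec | None = None,
    config: TrainConfig | None = None,
    val_data: tuple[np.ndarray, Sequence[int]] | None = None,
) -> TrainedModel:
    """Train one family's binary classifier on a balanced masked feature matrix.

    ``y`` holds 0/1 labels (1 = member of the target family). Raises if only
    one class is present.

    ``val_data``, when given, is an explicit ``(X_val, y_val)`` validation set
    used for early stopping instead of an internal 10% fold; its loss is
    class-balanced so a negative-heavy validation set (e.g. one enriched with
    corpus-wide negatives, the distribution the classifier actually faces at
    inference) does not drown out the positives.
    """
    X = np.asarray(X, dtype=np.float64)
    y_arr = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    if len(y_arr) != X.shape[0]:
        raise ValueError("y length does not match X rows")
    if len(np.unique(y_arr)) < 2:
        raise ValueError("training labels contain a single class")
    if spec is None:
        spec = ClassifierSpec(input_dim=X.shape[1])
    if spec.input_dim != X.shape[1]:
        raise ValueError("spec.input_dim does not match X columns")
    config = config or TrainConfig()
    packed_val = None
    if val_data is not None:
        X_val = np.asarray(val_data[0], dtype=np.float64)
        t_val = np.asarray(val_data[1], dtype=np.float64).reshape(-1, 1)
        w_val = _balanced_weights(t_val[:, 0])
        packed_val = (X_val, t_val, w_val)
    return _fit(X, y_arr, spec, config, val_data=packed_val)


def _balanced_weights(classes: np.ndarray) -> np.ndarray:
    """Per-sample weights giving every class equal total mass."""
    values, counts = np.unique(classes, return_counts=True)
    share = {v: 1.0 / c for v, c in zip(values, counts)}
    return np.array([share[c] for c in classes])


def train_stacker(
    P: np.ndarray,
    labels: Sequence[str],
    families: Sequence[str],
    spec: ClassifierSpec | None = None,
    config: TrainConfig | None = None,
    class_weight: str | None = None,
) -> TrainedModel:
    """Train the stacking meta-classifier on base-learner probability vectors.

    ``P`` has one column per family in canonical order; ``labels`` are family
    names drawn from ``families``. The trained model's meta records the family
    order so the column convention is checkable at load time.

    With ``class_weight="balanced"`` each family contributes equal total loss
    mass regardless of its size; the default (None) weights every sequence
    equally.
    """
    P = np.asarray(P, dtype=np.float64)
    families = list(families)
    if P.shape[1] != len(families):
        raise ValueError(
            f"P has {P.shape[1]} columns but {len(families)} families given"
        )
    index = {f: i for i, f in enumerate(families)}
    try:
        y_idx = np.array([index[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc} not in family order") from exc
    one_hot = np.zeros((len(y_idx), len(families)))
    one_hot[np.arange(len(y_idx)), y_idx] = 1.0
    if spec is None:
        spec = ClassifierSpec(
            input_dim=len(families), output_dim=len(families), output="softmax"
        )
    if config is None:
        config = TrainConfig(input_noise=0.4, input_noise_mode="uniform")
    weight = _balanced_weights(y_idx) if class_weight == "balanced" else None
    model = _fit(P, one_hot, spec, config, sample_weight=weight)
    model.training_meta["families"] = families
    return model


@dataclass
class StackerEnsemble:
    """Softmax average of several identically configured stacker networks.

    Initialization variance makes a single meta-net's extrapolation outside
    the training manifold (e.g. a non-TF sequence where every base learner is
    quiet) erratic and occasionally overconfident; averaging the softmax
    outputs of a few seeds keeps confident regions confident while damping
    spurious certainty elsewhere.
    """

    members: list[TrainedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("StackerEnsemble needs at least one member")
        specs = {m.spec for m in self.members}
        if len(specs) != 1:
            raise ValueError("all stacker members must share one architecture")

    @property
    def spec(self) -> ClassifierSpec:
        return self.members[0].spec

    @property
    def training_meta(self) -> dict:
        return {
            "members": [m.training_meta for m in self.members],
            "families": self.members[0].training_meta.get("families"),
        }

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        for i, m in enumerate(self.members):
            m.save(prefix.parent / f"{prefix.name}_{i:02d}")

    @classmethod
    def load(cls, prefix: str | Path, n_members: int) -> "StackerEnsemble":
        prefix = Path(prefix)
        return cls(
            members=[
                TrainedModel.load(prefix.parent / f"{prefix.name}_{i:02d}")
                for i in range(n_members)
            ]
        )


def predict_proba(model: "TrainedModel | StackerEnsemble", X: np.ndarray) -> np.ndarray:
    """Deterministic inference (dropout off). Binary models return shape (n,);
    softmax models shape (n, n_families) with rows summing to 1. A
    :class:`StackerEnsemble` returns the mean of its members' outputs."""
    if isinstance(model, StackerEnsemble):
        return np.mean([predict_proba(m, X) for m in model.members], axis=0)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.spec.input_dim}"
        )
    p, _ = model.net.forward(X)
    return p[:, 0] if model.spec.output == "sigmoid" else p
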