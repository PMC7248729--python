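"""Shallow convolutional network for 5-way trait classification.

The classifier is deliberately small: automatic fecal-examination machines
and hand-held diagnosis devices rarely have the compute to run a deep
network, and in the controlled acquisition environment a 3-layer network
both converges faster and generalizes better than deep baselines.  The
default architecture is

    input 60 x 60 x 3 (pixel values scaled to [0, 1])
    -> [conv 3x3, same padding, ReLU, max-pool 2x2] x depth
       with 32, 64, 256 filters at depth 3
    -> flatten -> fully connected 256, ReLU, dropout
    -> fully connected 5 -> softmax

trained with Adam on the cross-entropy (logistic) loss.  For depth sweeps,
depths below 3 drop trailing conv blocks and depths above 3 append blocks
whose filter count doubles layer by layer (512, 1024, ...), stride kept
at 1.

Everything here is NumPy: im2col convolutions, explicit backprop, and an
Adam update, so training is deterministic given the seeds and runs on any
CPU.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix

from .errors import InvalidInputError

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ClassProbabilities",
    "ShallowCNN",
    "build_model",
    "relu",
    "softmax",
    "cross_entropy_loss",
    "train",
    "evaluate",
    "predict",
    "images_to_tensor",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_BASE_FILTERS = (32, 64, 256)


def default_filters(depth: int) -> tuple[int, ...]:
    """Filter counts per conv layer for a given depth.

    Depth 3 is the canonical (32, 64, 256); shallower networks drop
    trailing layers, deeper ones double the filter count layer by layer.
    """
    if depth < 1:
        raise InvalidInputError(f"depth must be >= 1, got {depth}")
    if depth <= 3:
        return _BASE_FILTERS[:depth]
    extra = tuple(_BASE_FILTERS[-1] * 2 ** (i + 1) for i in range(depth - 3))
    return _BASE_FILTERS + extra


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the shallow classifier.

    ``conv_filters`` defaults to the canonical schedule for ``depth``; the
    kernel is 3x3 throughout, the hidden fully connected layer is 256 wide
    and the output layer has one unit per trait class.
    """

    input_size: tuple[int, int, int] = (60, 60, 3)
    depth: int = 3
    conv_filters: tuple[int, ...] | None = None
    kernel_size: int = 3
    fc_size: int = 256
    num_classes: int = 5
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidInputError(f"depth must be >= 1, got {self.depth}")
        if self.conv_filters is None:
            object.__setattr__(self, "conv_filters", default_filters(self.depth))
        if len(self.conv_filters) != self.depth:
            raise InvalidInputError("conv_filters length must equal depth")
        if not (0 <= self.dropout_rate < 1):
            raise InvalidInputError("dropout_rate must be in [0, 1)")

    def spatial_trace(self) -> list[tuple[int, int]]:
        """(H, W) after each conv block; pooling halves (floor), skipped at size 1."""
        h, w = self.input_size[:2]
        trace = []
        for _ in range(self.depth):
            if min(h, w) >= 2:
                h, w = h // 2, w // 2
            trace.append((h, w))
        return trace


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam defaults; all config-exposed)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    early_stopping_patience: int | None = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise InvalidInputError("learning_rate must be >= 0; batch_size, epochs >= 1")


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax output for one sample plus the argmax decision."""

    probs: np.ndarray
    predicted: int


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(x, 0)


def softmax(y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax: exp(y - max) normalized along ``axis``."""
    y = np.asarray(y, dtype=np.float64)
    shifted = y - y.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss(p_true: np.ndarray, q_pred: np.ndarray, eps: float = 1e-12) -> float:
    """Mean over the batch of -sum_c p_c log q_c.

    ``p_true`` is a one-hot batch, ``q_pred`` the predicted probabilities.
    Zero predicted probability at the true class is clamped at ``eps``
    (and logged) rather than raising.
    """
    p = np.asarray(p_true, dtype=np.float64)
    q = np.asarray(q_pred, dtype=np.float64)
    if p.shape != q.shape:
        raise InvalidInputError("p_true and q_pred must have the same shape")
    if np.any((q <= 0) & (p > 0)):
        logger.warning("zero predicted probability at a true class; clamping at %g", eps)
    per_sample = -(p * np.log(np.clip(q, eps, None))).sum(axis=-1)
    return float(per_sample.mean())


# ---------------------------------------------------------------------------
# layer primitives (float32 im2col convolutions with explicit backprop)
# ---------------------------------------------------------------------------

def _conv2d_same(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 same-padding cross-correlation.  Returns (output, im2col matrix)."""
    n, h, wd, _ = x.shape
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * wd, k * k * x.shape[3]
    )
    out = cols @ w.reshape(-1, w.shape[3])
    return out.reshape(n, h, wd, w.shape[3]), cols


def _conv2d_same_backward_input(dout: np.ndarray, w: np.ndarray) -> np.ndarray:
    # gradient wrt input = same-padding correlation with the spatially
    # flipped kernel, input/output channels swapped
    w_flip = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
    dx, _ = _conv2d_same(dout, w_flip)
    return dx


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 stride-2 max pooling (floor on odd sizes).  Returns (out, argmax)."""
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    xr = (
        x[:, : ho * 2, : wo * 2]
        .reshape(n, ho, 2, wo, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, ho, wo, c, 4)
    )
    idx = xr.argmax(axis=4)
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, x_shape: tuple) -> np.ndarray:
    n, h, w, c = x_shape
    ho, wo = h // 2, w // 2
    dxr = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=4)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : ho * 2, : wo * 2] = (
        dxr.reshape(n, ho, wo, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, ho * 2, wo * 2, c)
    )
    return dx


class ShallowCNN:
    """The shallow classifier with explicit forward/backward passes.

    Parameters live in ``self.params`` (a flat dict of float32 arrays);
    weight initialization is He-normal from the given seed, biases start
    at zero.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)  # float32 for speed; float64 for grad checks
        rng = np.random.default_rng(seed)
        k = cfg.kernel_size
        self.params: dict[str, np.ndarray] = {}
        c_in = cfg.input_size[2]
        for i, f in enumerate(cfg.conv_filters):
            fan_in = k * k * c_in
            self.params[f"convW{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, f)
            ).astype(self.dtype)
            self.params[f"convb{i}"] = np.zeros(f, dtype=self.dtype)
            c_in = f
        h, w = cfg.spatial_trace()[-1]
        self.flat_dim = h * w * cfg.conv_filters[-1]
        self.params["fcW1"] = rng.normal(
            0.0, np.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, cfg.fc_size)
        ).astype(self.dtype)
        self.params["fcb1"] = np.zeros(cfg.fc_size, dtype=self.dtype)
        self.params["fcW2"] = rng.normal(
            0.0, np.sqrt(2.0 / cfg.fc_size), size=(cfg.fc_size, cfg.num_classes)
        ).astype(self.dtype)
        self.params["fcb2"] = np.zeros(cfg.num_classes, dtype=self.dtype)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Compute logits for a batch ``x`` of shape (N, H, W, 3) in [0, 1].

        With ``training=True`` dropout is active (requires ``rng``) and the
        cache needed by :meth:`backward` is populated.
        """
        x = np.asarray(x, dtype=self.dtype)
        cache: dict = {"conv": []}
        for i in range(self.cfg.depth):
            w, b = self.params[f"convW{i}"], self.params[f"convb{i}"]
            pre, cols = _conv2d_same(x, w)
            pre += b
            act = relu(pre)
            if min(act.shape[1], act.shape[2]) >= 2:
                pooled, pool_idx = _maxpool2(act)
            else:
                pooled, pool_idx = act, None
            cache["conv"].append(
                {"cols": cols if training else None, "relu_mask": pre > 0,
                 "pool_idx": pool_idx, "act_shape": act.shape}
            )
            x = pooled
        n = x.shape[0]
        flat = x.reshape(n, self.flat_dim)
        h1 = flat @ self.params["fcW1"] + self.params["fcb1"]
        a1 = relu(h1)
        if training and self.cfg.dropout_rate > 0:
            if rng is None:
                raise InvalidInputError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.cfg.dropout_rate
            drop = (rng.random(a1.shape) < keep).astype(self.dtype) / keep
        else:
            drop = None
        d1 = a1 * drop if drop is not None else a1
        logits = d1 @ self.params["fcW2"] + self.params["fcb2"]
        cache.update(flat=flat, h1_mask=h1 > 0, d1=d1, drop=drop)
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class probabilities for a stack of images (dropout inactive)."""
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the batch loss wrt every parameter."""
        grads: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(self.dtype)
        grads["fcW2"] = cache["d1"].T @ dlogits
        grads["fcb2"] = dlogits.sum(axis=0)
        dd1 = dlogits @ self.params["fcW2"].T
        if cache["drop"] is not None:
            dd1 = dd1 * cache["drop"]
        dh1 = dd1 * cache["h1_mask"]
        grads["fcW1"] = cache["flat"].T @ dh1
        grads["fcb1"] = dh1.sum(axis=0)
        dflat = dh1 @ self.params["fcW1"].T
        h, w = self.cfg.spatial_trace()[-1]
        dx = dflat.reshape(-1, h, w, self.cfg.conv_filters[-1])
        for i in reversed(range(self.cfg.depth)):
            c = cache["conv"][i]
            if c["pool_idx"] is not None:
                dx = _maxpool2_backward(dx, c["pool_idx"], c["act_shape"])
            dpre = dx * c["relu_mask"]
            w_i = self.params[f"convW{i}"]
            grads[f"convb{i}"] = dpre.sum(axis=(0, 1, 2))
            grads[f"convW{i}"] = (
                c["cols"].T @ dpre.reshape(-1, w_i.shape[3])
            ).reshape(w_i.shape)
            if i > 0:  # input gradient of the first layer is never needed
                dx = _conv2d_same_backward_input(dpre, w_i)
        return grads


def build_model(cfg: NetworkConfig | None = None, seed: int = 0) -> ShallowCNN:
    """Construct a :class:`ShallowCNN` and log its parameter count."""
    cfg = cfg or NetworkConfig()
    model = ShallowCNN(cfg, seed=seed)
    logger.info(
        "built shallow CNN: depth=%d filters=%s params=%d",
        cfg.depth, cfg.conv_filters, model.parameter_count(),
    )
    return model


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= (
                c.learning_rate * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.eps)
            ).astype(params[k].dtype)


def images_to_tensor(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack uint8 images into a float32 (N, H, W, 3) tensor scaled to [0, 1]."""
    arr = np.stack([np.asarray(im) for im in images]).astype(np.float32)
    return arr / 255.0


def _one_hot(y: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[np.asarray(y, dtype=int)]


def train(
    model: ShallowCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """Optimize the model in place with Adam; returns the epoch history.

    Each history row holds the mean training loss and accuracy of the
    epoch (and validation metrics when a validation set is given, in which
    case early stopping on validation loss is applied and the best weights
    are restored).  All shuffling and dropout randomness flows from
    ``cfg.seed``, so two runs from identically initialized models produce
    identical weights.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise InvalidInputError("empty training set")
    if len(np.unique(y_train)) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    onehot = _one_hot(y_train, model.cfg.num_classes)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg)
    history: list[dict] = []
    best = None
    patience_left = cfg.early_stopping_patience

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, pb = x_train[idx], onehot[idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            probs = softmax(logits)
            losses.append(cross_entropy_loss(pb, probs))
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
            dlogits = (probs - pb) / len(idx)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads)
        row = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / len(x_train),
        }
        if x_val is not None and y_val is not None:
            val_probs = model.predict_proba(np.asarray(x_val, dtype=np.float32))
            row["val_loss"] = cross_entropy_loss(
                _one_hot(y_val, model.cfg.num_classes), val_probs
            )
            row["val_accuracy"] = float(
                (val_probs.argmax(axis=1) == np.asarray(y_val)).mean()
            )
            if cfg.early_stopping_patience is not None:
                if best is None or row["val_loss"] < best[0]:
                    best = (row["val_loss"], {k: v.copy() for k, v in model.params.items()})
                    patience_left = cfg.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        history.append(row)
                        model.params.update(best[1])
                        break
        history.append(row)
    if best is not None and cfg.early_stopping_patience is not None:
        model.params.update(best[1])
    return history


def evaluate(model: ShallowCNN, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true class, columns = predicted)."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if len(x) == 0:
        raise InvalidInputError("empty evaluation set")
    preds = model.predict_proba(x).argmax(axis=1)
    cm = confusion_matrix(y, preds, labels=np.arange(model.cfg.num_classes))
    return float(np.trace(cm) / cm.sum()), cm


def predict(model: ShallowCNN, image: np.ndarray) -> ClassProbabilities:
    """Class probabilities for a single preprocessed (H, W, 3) image."""
    x = images_to_tensor([image])
    probs = model.predict_proba(x)[0]
    return ClassProbabilities(probs=probs, predicted=int(probs.argmax()))


def save_model(model: ShallowCNN, path: str | Path) -> None:
    """Persist parameters and architecture to a single .npz file."""
    cfg = model.cfg
    meta = {
        "input_size": list(cfg.input_size), "depth": cfg.depth,
        "conv_filters": list(cfg.conv_filters), "kernel_size": cfg.kernel_size,
        "fc_size": cfg.fc_size, "num_classes": cfg.num_classes,
        "dropout_rate": cfg.dropout_rate,
    }
    np.savez(path, _config=json.dumps(meta), **model.params)


def load_model(path: str | Path) -> ShallowCNN:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_config"]))
        cfg = NetworkConfig(
            input_size=tuple(meta["input_size"]), depth=meta["depth"],
            conv_filters=tuple(meta["conv_filters"]), kernel_size=meta["kernel_size"],
            fc_size=meta["fc_size"], num_classes=meta["num_classes"],
            dropout_rate=meta["dropout_rate"],
        )
        model = ShallowCNN(cfg, seed=0)
        for k in model.params:
            model.params[k] = data[k].copy()
    return model
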