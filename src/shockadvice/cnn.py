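"""The parameterized 1-D CNN family: builder, trainer, feature extractor.

The family is indexed by five selection parameters:

* ``ns`` — number of sections; section ``s`` holds convolutions with
  ``10 * 2**(s-1)`` filters and ends in a max-pooling layer,
* ``nd`` — blocks per section, a block being conv(kernel 101, stride 1,
  padding 50) + ReLU,
* ``lr`` — SGD learning rate,
* ``momentum`` — SGD momentum (Mo),
* ``dropout`` — dropout probability on the first fully connected layer (Re).

After the sections: flatten -> FC(100) -> ReLU -> dropout -> FC(2) -> softmax.
The selected shock-advice network is ``ns=3, nd=1`` on a 2000-sample, 3-channel
input (pECG / SH / NSH), giving per-section filter counts 10/20/40, pooled
temporal lengths 995/493/242, and a 9680-wide flatten into the 100-unit FC.
Used as a full classifier (fCNN) the softmax output decides; used as a feature
extractor (CNNE) the 100 post-ReLU activations of the first FC are the deep
feature vector for a secondary conventional classifier.

Convolutions run via the FFT (cross-correlation in the frequency domain), in
both the forward and the backward pass; training is plain SGD with momentum on
the softmax cross-entropy, deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .records import ChannelStack

__all__ = [
    "CnnConfig",
    "CnnModel",
    "build_cnne",
    "forward_shapes",
    "train_cnne",
    "extract_features",
    "predict_fcnn",
    "count_parameters",
    "save_model",
    "load_model",
]

KERNEL = 101
PAD = 50
POOL_K = 11
POOL_S = 2
N_CLASSES = 2
BASE_FILTERS = 10


@dataclass
class CnnConfig:
    """The five selection parameters plus input geometry and training defaults."""

    ns: int = 3
    nd: int = 1
    lr: float = 0.005
    momentum: float = 0.9
    dropout: float = 0.15
    input_len: int = 2000
    n_channels: int = 3
    fc_width: int = 100
    epochs: int = 40
    batch_size: int = 32
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.ns < 1 or self.nd < 1:
            raise ValueError("ns and nd must be >= 1")
        if not 0.0 < self.lr < 1.0 and self.lr != 0.0:
            raise ValueError(f"lr must be in [0, 1), got {self.lr}")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        trace = forward_shapes(self)
        if trace[-1][1] < 1:
            raise ValueError(
                f"ns={self.ns} pooling stages collapse a {self.input_len}-sample "
                "input to zero temporal length"
            )

    def filters(self, section: int) -> int:
        """Filter count of 1-based section ``section``: 10 * 2**(s-1)."""
        return BASE_FILTERS * 2 ** (section - 1)


def forward_shapes(config: CnnConfig) -> list[tuple[str, int, int]]:
    """Per-layer (name, temporal length, channels) trace through the sections.

    conv: L -> floor((L + 2*50 - 101)/1) + 1 = L;  pool: L -> floor((L-11)/2)+1.
    """
    trace = [("input", config.input_len, config.n_channels)]
    length = config.input_len
    channels = config.n_channels
    for s in range(1, config.ns + 1):
        f = BASE_FILTERS * 2 ** (s - 1)
        for d in range(1, config.nd + 1):
            length = (length + 2 * PAD - KERNEL) + 1
            channels = f
            trace.append((f"conv{s}.{d}", length, channels))
        length = (length - POOL_K) // POOL_S + 1
        trace.append((f"pool{s}", length, channels))
        if length < 1:
            break
    return trace


def flatten_width(config: CnnConfig) -> int:
    """Width of the flattened feature map entering the first FC layer."""
    _, length, channels = forward_shapes(config)[-1]
    return length * channels


# ---------------------------------------------------------------------------
# layers


class _Conv1d:
    """Same-length 1-D cross-correlation via the FFT; stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype):
        scale = np.sqrt(2.0 / (c_in * KERNEL))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, KERNEL)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b_, c, length = x.shape
        # zero-padding to a fast FFT length preserves the linear correlation
        n = next_fast_len(length + 2 * PAD)
        xp = np.zeros((b_, c, n), dtype=x.dtype)
        xp[:, :, PAD:PAD + length] = x
        xf = rfft(xp)
        wf = rfft(self.w, n)
        yf = np.einsum("bcn,fcn->bfn", xf, wf.conj())
        y = irfft(yf, n)[:, :, :length] + self.b[:, None]
        if train:
            self._cache = (xf, n, length)
        return y.astype(x.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, n, length = self._cache
        dyp = np.zeros(dy.shape[:2] + (n,), dtype=dy.dtype)
        dyp[:, :, :length] = dy
        dyf = rfft(dyp)
        wf = rfft(self.w, n)
        dxf = np.einsum("bfn,fcn->bcn", dyf, wf)
        dx = irfft(dxf, n)[:, :, PAD:PAD + length]
        dwf = np.einsum("bcn,bfn->fcn", xf, dyf.conj())
        self.dw = irfft(dwf, n)[:, :, :KERNEL].astype(self.w.dtype, copy=False)
        self.db = dy.sum(axis=(0, 2)).astype(self.b.dtype, copy=False)
        self._cache = None
        return dx.astype(dy.dtype, copy=False)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool:
    """Max pooling, kernel 11, stride 2, no padding."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(x, POOL_K, axis=-1)[..., ::POOL_S, :]
        if train:
            self._argmax = win.argmax(axis=-1)
            self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b_, c, lout = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        pos = self._argmax + POOL_S * np.arange(lout)  # (b, c, lout) input indices
        flat_off = (np.arange(b_)[:, None, None] * c + np.arange(c)[None, :, None]) \
            * self._in_shape[-1]
        np.add.at(dx.reshape(-1), (flat_off + pos).ravel(), dy.ravel())
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.w

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return dy
        return dy * self._mask.astype(dy.dtype)

    def params(self):
        return []

    def grads(self):
        return []


# ---------------------------------------------------------------------------
# model


@dataclass
class CnnModel:
    """A built (and possibly trained) network of the (ns, nd) family."""

    config: CnnConfig
    layers: list
    feature_layer_idx: int       # index *after* which the feature vector is read
    seed: int
    loss_log: list[float] = field(default_factory=list)
    train_record_ids: set[str] = field(default_factory=set)
    trained: bool = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def layer_summary(self) -> list[str]:
        return [type(l).__name__.lstrip("_") for l in self.layers]


def build_cnne(config: CnnConfig | None = None, seed: int = 0,
               dtype=np.float32) -> CnnModel:
    """Assemble the network for a configuration with seeded He initialization."""
    if config is None:
        config = CnnConfig()
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = config.n_channels
    for s in range(1, config.ns + 1):
        f = config.filters(s)
        for _ in range(config.nd):
            layers.append(_Conv1d(c_in, f, rng, dtype))
            layers.append(_ReLU())
            c_in = f
        layers.append(_MaxPool())
    layers.append(_Flatten())
    layers.append(_Dense(flatten_width(config), config.fc_width, rng, dtype))
    layers.append(_ReLU())
    feature_idx = len(layers) - 1
    layers.append(_Dropout(config.dropout))
    layers.append(_Dense(config.fc_width, N_CLASSES, rng, dtype))
    return CnnModel(config=config, layers=layers, feature_layer_idx=feature_idx,
                    seed=seed)


def count_parameters(model_or_config: CnnModel | CnnConfig) -> int:
    if isinstance(model_or_config, CnnConfig):
        model = build_cnne(model_or_config)
    else:
        model = model_or_config
    return sum(int(np.prod(p.shape)) for layer in model.layers
               for _, p in layer.params())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _stacks_to_arrays(data, dtype) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(data, tuple):
        x, y = data
        return np.asarray(x, dtype=dtype), np.asarray(y, dtype=int), []
    xs, ys, rids = [], [], []
    for st in data:
        if not isinstance(st, ChannelStack):
            raise TypeError("expected ChannelStacks or an (X, y) tuple")
        xs.append(st.as_array())
        ys.append(st.label)
        rids.append(st.record_id)
    return np.asarray(xs, dtype=dtype), np.asarray(ys, dtype=int), rids


def train_cnne(
    model: CnnModel,
    data,
    epochs: int | None = None,
    batch_size: int | None = None,
    seed: int = 0,
) -> CnnModel:
    """Train in place by SGD with momentum on softmax cross-entropy.

    ``data`` is a list of labeled ChannelStacks or an ``(X, y)`` tuple with
    X of shape (n, channels, input_len).  Deterministic given the seed (which
    drives shuffling and dropout; weight initialization was seeded at build
    time).  Raises on single-class data and aborts on NaN loss.
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    dtype = model.layers[-1].w.dtype
    x, y, rids = _stacks_to_arrays(data, dtype)
    if x.shape[1:] != (cfg.n_channels, cfg.input_len):
        raise ValueError(
            f"data shape {x.shape[1:]} does not match configured input "
            f"({cfg.n_channels}, {cfg.input_len})"
        )
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(seed)
    for layer in model.layers:
        if isinstance(layer, _Dropout):
            layer.rng = rng

    if cfg.class_weighting:
        freq = np.bincount(y, minlength=N_CLASSES).astype(float)
        cls_w = np.where(freq > 0, len(y) / (N_CLASSES * np.maximum(freq, 1)), 0.0)
    else:
        cls_w = np.ones(N_CLASSES)

    velocity = [[np.zeros_like(p) for _, p in layer.params()] for layer in model.layers]
    n = len(y)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits.astype(np.float64))
            w = cls_w[yb]
            losses = -np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-12))
            loss = float((w * losses).sum() / w.sum())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {_epoch} "
                    f"(lr={cfg.lr}, momentum={cfg.momentum})"
                )
            epoch_loss += loss * len(yb)
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (w / w.sum())[:, None]
            grad = dlogits.astype(dtype)
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            for layer, vel in zip(model.layers, velocity):
                for (name_p, p), g, v in zip(layer.params(), layer.grads(), vel):
                    v *= cfg.momentum
                    v -= cfg.lr * g
                    p += v
        model.loss_log.append(epoch_loss / n)
    model.trained = True
    model.train_record_ids.update(r for r in rids if r)
    return model


def _as_batch(stack, config: CnnConfig, dtype) -> np.ndarray:
    if isinstance(stack, ChannelStack):
        arr = stack.as_array()[None]
    elif isinstance(stack, (list, tuple)) and stack and isinstance(stack[0], ChannelStack):
        arr = np.stack([st.as_array() for st in stack])
    else:
        arr = np.asarray(stack, dtype=dtype)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.shape[1:] != (config.n_channels, config.input_len):
        raise ValueError(
            f"input shape {arr.shape[1:]} does not match configured "
            f"({config.n_channels}, {config.input_len})"
        )
    return arr.astype(dtype, copy=False)


def extract_features(model: CnnModel, stack) -> np.ndarray:
    """The deep feature vector: first-FC activations post-ReLU, dropout off.

    Accepts one ChannelStack / (3, L) array (returns a (fc_width,) vector) or
    a batch (n, 3, L) (returns (n, fc_width)).  Pure function of (weights,
    input).
    """
    dtype = model.layers[-1].w.dtype
    single = isinstance(stack, ChannelStack) or (
        not isinstance(stack, (list, tuple)) and np.asarray(stack).ndim == 2
    )
    x = _as_batch(stack, model.config, dtype)
    for layer in model.layers[: model.feature_layer_idx + 1]:
        x = layer.forward(x, train=False)
    return x[0] if single else x


def predict_fcnn(model: CnnModel, stack) -> tuple[np.ndarray, np.ndarray]:
    """Full-CNN classification: (labels, softmax probabilities)."""
    dtype = model.layers[-1].w.dtype
    single = isinstance(stack, ChannelStack) or (
        not isinstance(stack, (list, tuple)) and np.asarray(stack).ndim == 2
    )
    x = _as_batch(stack, model.config, dtype)
    probs = _softmax(model.forward(x, train=False).astype(np.float64))
    labels = probs.argmax(axis=1)
    return (int(labels[0]), probs[0]) if single else (labels, probs)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: CnnModel, path: str | Path) -> None:
    """Self-describing archive: config + weights + seed + training log."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.layers):
        for name, p in layer.params():
            arrays[f"layer{i}_{name}"] = p
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "loss_log": model.loss_log,
        "train_record_ids": sorted(model.train_record_ids),
        "trained": model.trained,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> CnnModel:
    with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_cnne(CnnConfig(**meta["config"]), seed=meta["seed"])
        for i, layer in enumerate(model.layers):
            for name, p in layer.params():
                p[...] = data[f"layer{i}_{name}"]
    model.loss_log = list(meta["loss_log"])
    model.train_record_ids = set(meta["train_record_ids"])
    model.trained = meta["trained"]
    return model
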