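"""Parallel morphology + timing convolutional beat classifier.

The classifier fuses two information sources that a cardiologist also reads
jointly: the *shape* of each beat (two leads, 0.5 s either side of the S
peak) and its *timing* relative to the surrounding rhythm (a 20 s binary
vector of detected beats at 100 Hz).  The morphology input feeds two parallel
convolutional paths with different receptive fields; each path is two
[conv -> batch-norm -> ReLU -> dropout] blocks with a residual shortcut that
max-pools the path input by the combined stride and is added before
flattening.  Convolutions span samples only, never leads, so the leads do
not interact before the fully connected stage.  The timing input feeds two
1D conv + dropout layers.  Flattened morphology paths share one dense layer,
the timing path gets its own, and the concatenation passes through a final
dense layer into a 4-class softmax.  Setting ``use_timing_path=False`` gives
the morphology-only ablation variant.

Everything — layers, backprop, Adam, L2 — is implemented on numpy, which
keeps training bit-reproducible from a seed on any machine.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvBlockSpec",
    "NetworkConfig",
    "TrainConfig",
    "ParallelCNN",
    "build_network",
    "train",
    "transfer",
    "predict",
    "ensemble_predict",
    "table_eecg_config",
    "table_mitbih_config",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block row: stride factor, kernel half-size basis, filters.

    The convolution kernel spans ``2 * convolution_width`` samples and slides
    with ``subsampling`` stride.
    """

    subsampling: int
    convolution_width: int
    filters: int

    def __post_init__(self) -> None:
        if min(self.subsampling, self.convolution_width, self.filters) < 1:
            raise ValueError("conv block parameters must all be >= 1")


@dataclass(frozen=True)
class NetworkConfig:
    morph_path_1: tuple = (ConvBlockSpec(8, 10, 16), ConvBlockSpec(4, 50, 64))
    morph_path_2: tuple = (ConvBlockSpec(2, 30, 8), ConvBlockSpec(16, 20, 64))
    timing_path: tuple = (ConvBlockSpec(32, 50, 64), ConvBlockSpec(16, 30, 4))
    dense_units: int = 512
    final_dense_units: int = 32
    dropout: float = 0.2          # fraction of units zeroed (1 - p)
    l2_lambda: float = 0.001
    use_timing_path: bool = True
    n_classes: int = 4
    morph_width: int = 500
    timing_len: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout fraction must lie in [0, 1)")
        if self.n_classes != 4:
            raise ValueError("the classifier is a 4-class model")


def table_eecg_config(**overrides) -> NetworkConfig:
    """The GA-optimized equine architecture."""
    return replace(NetworkConfig(), **overrides)


def table_mitbih_config(**overrides) -> NetworkConfig:
    """The GA-optimized human (MIT-BIH) architecture."""
    cfg = NetworkConfig(
        morph_path_1=(ConvBlockSpec(4, 60, 16), ConvBlockSpec(16, 30, 16)),
        morph_path_2=(ConvBlockSpec(2, 20, 40), ConvBlockSpec(16, 20, 32)),
        timing_path=(ConvBlockSpec(128, 300, 4), ConvBlockSpec(8, 100, 8)),
    )
    return replace(cfg, **overrides)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.0001
    batch_size: int = 500
    epochs: int = 20
    early_stop_patience: int | None = None  # on training accuracy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")


#: GA inner-loop training preset: long budget, early stop on training accuracy.
GA_TRAIN_PRESET = TrainConfig(epochs=50, early_stop_patience=3)


# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad", "l2", "m", "v")

    def __init__(self, value: np.ndarray, l2: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.l2 = l2
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Layer:
    trainable = True

    def params(self) -> list[Param]:
        return []


class Conv1D(_Layer):
    """Same-padded strided 1D convolution over (B, C, L) tensors."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, kernel)), l2=True)
        self.b = Param(np.zeros(cout))
        self.kernel, self.stride = kernel, stride

    def params(self):
        return [self.W, self.b]

    def out_len(self, L: int) -> int:
        return -(-L // self.stride)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        O = self.out_len(L)
        total = max(0, (O - 1) * self.stride + self.kernel - L)
        pl = total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, total - pl)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        self._cache = (win, xp.shape, pl, L)
        return np.einsum("bcok,fck->bfo", win, self.W.value) + self.b.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, xp_shape, pl, L = self._cache
        self.b.grad += dy.sum(axis=(0, 2))
        self.W.grad += np.einsum("bfo,bcok->fck", dy, win)
        dxp = np.zeros(xp_shape)
        O = dy.shape[2]
        for i in range(self.kernel):
            dxp[:, :, i: i + self.stride * O: self.stride] += \
                np.einsum("bfo,fc->bco", dy, self.W.value[:, :, i])
        return dxp[:, :, pl: pl + L]


class BatchNorm1D(_Layer):
    """Per-channel batch normalization over (B, C, L); frozen layers run in
    inference mode and leave their running statistics untouched."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training and self.trainable:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) / std[:, None]
        self._cache = (xhat, std, x.shape)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[:, None]
        if not self.trainable:
            return dxhat / std[:, None]
        N = shape[0] * shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (dxhat - s1 / N - xhat * s2 / N) / std[:, None]


class ReLU(_Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(_Layer):
    """Inverted dropout; active only while training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1D(_Layer):
    """Ceil-mode max pooling by an integer factor (the residual shortcut)."""

    def __init__(self, factor: int):
        self.factor = factor

    def out_len(self, L: int) -> int:
        return -(-L // self.factor)

    def forward(self, x, training=False):
        B, C, L = x.shape
        O = self.out_len(L)
        pad = O * self.factor - L
        xp = np.pad(x, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
        blocks = xp.reshape(B, C, O, self.factor)
        self._arg = blocks.argmax(axis=3)
        self._shape = (B, C, L, O, pad)
        return blocks.max(axis=3)

    def backward(self, dy):
        B, C, L, O, pad = self._shape
        dxp = np.zeros((B, C, O, self.factor))
        bi, ci, oi = np.indices((B, C, O))
        dxp[bi, ci, oi, self._arg] = dy
        dxp = dxp.reshape(B, C, O * self.factor)
        return dxp[:, :, :L]


class Dense(_Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)), l2=True)
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


# ---------------------------------------------------------------------------
# the parallel architecture


class _ConvBlock:
    """conv -> (batch-norm) -> (ReLU) -> dropout."""

    def __init__(self, cin: int, spec: ConvBlockSpec, dropout: float,
                 rng: np.random.Generator, batchnorm: bool, relu: bool):
        self.conv = Conv1D(cin, spec.filters, 2 * spec.convolution_width,
                           spec.subsampling, rng)
        self.bn = BatchNorm1D(spec.filters) if batchnorm else None
        self.relu = ReLU() if relu else None
        self.drop = Dropout(dropout, rng)

    def layers(self):
        return [ly for ly in (self.conv, self.bn, self.relu, self.drop) if ly is not None]

    def forward(self, x, training):
        h = self.conv.forward(x, training)
        if self.bn is not None:
            h = self.bn.forward(h, training)
        if self.relu is not None:
            h = self.relu.forward(h, training)
        return self.drop.forward(h, training)

    def backward(self, dy):
        dy = self.drop.backward(dy)
        if self.relu is not None:
            dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)


class _MorphPath:
    """Two conv blocks plus the max-pool residual shortcut, per lead."""

    def __init__(self, specs, dropout: float, rng: np.random.Generator, width: int):
        s1, s2 = specs
        self.block1 = _ConvBlock(1, s1, dropout, rng, batchnorm=True, relu=True)
        self.block2 = _ConvBlock(s1.filters, s2, dropout, rng, batchnorm=True, relu=True)
        self.pool = MaxPool1D(s1.subsampling * s2.subsampling)
        self.proj = Conv1D(1, s2.filters, 1, 1, rng)  # 1x1 conv matches channels
        stack_len = self.block2.conv.out_len(self.block1.conv.out_len(width))
        if self.pool.out_len(width) != stack_len:
            raise ValueError(
                "residual shortcut length does not match the conv stack output "
                f"({self.pool.out_len(width)} vs {stack_len}); the shortcut pool "
                "factor must equal the product of the conv subsampling factors")
        self.out_shape = (s2.filters, stack_len)

    def layers(self):
        return self.block1.layers() + self.block2.layers() + [self.pool, self.proj]

    def conv_layers(self):
        return [self.block1.conv, self.block1.bn, self.block2.conv, self.block2.bn,
                self.proj]

    def forward(self, x, training):
        h = self.block2.forward(self.block1.forward(x, training), training)
        sc = self.proj.forward(self.pool.forward(x, training), training)
        return h + sc

    def backward(self, dy):
        dx = self.block1.backward(self.block2.backward(dy))
        dsc = self.pool.backward(self.proj.backward(dy))
        return dx + dsc


class _TimingPath:
    """Two 1D conv + dropout layers (no batch-norm, no residual)."""

    def __init__(self, specs, dropout: float, rng: np.random.Generator, length: int):
        s1, s2 = specs
        self.block1 = _ConvBlock(1, s1, dropout, rng, batchnorm=False, relu=False)
        self.block2 = _ConvBlock(s1.filters, s2, dropout, rng, batchnorm=False,
                                 relu=False)
        out_len = self.block2.conv.out_len(self.block1.conv.out_len(length))
        self.out_shape = (s2.filters, out_len)

    def layers(self):
        return self.block1.layers() + self.block2.layers()

    def conv_layers(self):
        return [self.block1.conv, self.block2.conv]

    def forward(self, x, training):
        return self.block2.forward(self.block1.forward(x, training), training)

    def backward(self, dy):
        return self.block1.backward(self.block2.backward(dy))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ParallelCNN:
    """The assembled classifier; see the module docstring for the topology."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.provenance: dict = {"seed": seed}
        rng = self.rng
        W, T = config.morph_width, config.timing_len
        self.path1 = _MorphPath(config.morph_path_1, config.dropout, rng, W)
        self.path2 = _MorphPath(config.morph_path_2, config.dropout, rng, W)
        morph_flat = 2 * (self.path1.out_shape[0] * self.path1.out_shape[1]
                          + self.path2.out_shape[0] * self.path2.out_shape[1])
        self.morph_dense = Dense(morph_flat, config.dense_units, rng)
        self.morph_relu = ReLU()
        if config.use_timing_path:
            self.timing = _TimingPath(config.timing_path, config.dropout, rng, T)
            self.timing_dense = Dense(self.timing.out_shape[0] * self.timing.out_shape[1],
                                      config.dense_units, rng)
            self.timing_relu = ReLU()
            head_in = 2 * config.dense_units
        else:
            self.timing = None
            head_in = config.dense_units
        self.head = Dense(head_in, config.final_dense_units, rng)
        self.head_relu = ReLU()
        self.out = Dense(config.final_dense_units, config.n_classes, rng)
        self.training_history: list[dict] = []

    # -- plumbing -----------------------------------------------------------

    def _dense_layers(self):
        layers = [self.morph_dense, self.head, self.out]
        if self.timing is not None:
            layers.append(self.timing_dense)
        return layers

    def _conv_layers(self):
        layers = self.path1.conv_layers() + self.path2.conv_layers()
        if self.timing is not None:
            layers += self.timing.conv_layers()
        return [ly for ly in layers if ly is not None]

    def _all_layers(self):
        layers = self.path1.layers() + self.path2.layers()
        if self.timing is not None:
            layers += self.timing.layers() + [self.timing_dense, self.timing_relu]
        layers += [self.morph_dense, self.morph_relu, self.head, self.head_relu, self.out]
        return layers

    def parameters(self) -> list[tuple[_Layer, Param]]:
        out = []
        for ly in self._all_layers():
            for p in ly.params():
                out.append((ly, p))
        return out

    @property
    def num_params(self) -> int:
        return sum(p.value.size for _, p in self.parameters())

    def set_feature_layers_trainable(self, trainable: bool) -> None:
        """Freeze/unfreeze every convolutional and batch-norm layer (the
        feature extractor); dense layers stay trainable."""
        for ly in self._conv_layers():
            ly.trainable = trainable

    def conv_param_bytes(self) -> bytes:
        """Serialized bytes of all conv/batch-norm parameters and statistics
        (the freeze-mode transfer contract checks these for identity)."""
        buf = io.BytesIO()
        for ly in self._conv_layers():
            for p in ly.params():
                buf.write(np.ascontiguousarray(p.value).tobytes())
            if isinstance(ly, BatchNorm1D):
                for arr in ly.state():
                    buf.write(np.ascontiguousarray(arr).tobytes())
        return zlib.compress(buf.getvalue(), level=1)

    # -- forward / backward -------------------------------------------------

    def forward(self, morph: np.ndarray, timing: np.ndarray | None,
                training: bool = False) -> np.ndarray:
        """Logits for a batch; morph (B, 2, W), timing (B, T)."""
        morph = np.asarray(morph, dtype=float)
        B = morph.shape[0]
        if morph.shape[1:] != (2, self.config.morph_width):
            raise ValueError(
                f"morphology input must be (B, 2, {self.config.morph_width}), "
                f"got {morph.shape}")
        folded = morph.reshape(B * 2, 1, self.config.morph_width)
        h1 = self.path1.forward(folded, training).reshape(B, -1)
        h2 = self.path2.forward(folded, training).reshape(B, -1)
        self._morph_split = (h1.shape[1], h2.shape[1])
        m = self.morph_relu.forward(
            self.morph_dense.forward(np.concatenate([h1, h2], axis=1), training), training)
        if self.timing is not None:
            if timing is None:
                raise ValueError("this model needs the timing input")
            timing = np.asarray(timing, dtype=float)
            if timing.shape != (B, self.config.timing_len):
                raise ValueError(
                    f"timing input must be (B, {self.config.timing_len}), got {timing.shape}")
            ht = self.timing.forward(timing[:, None, :], training).reshape(B, -1)
            t = self.timing_relu.forward(self.timing_dense.forward(ht, training), training)
            fused = np.concatenate([m, t], axis=1)
        else:
            fused = m
        h = self.head_relu.forward(self.head.forward(fused, training), training)
        return self.out.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        B = dlogits.shape[0]
        d = self.head_relu.backward(self.out.backward(dlogits))
        d = self.head.backward(d)
        du = self.config.dense_units
        if self.timing is not None:
            dm, dt = d[:, :du], d[:, du:]
            dt = self.timing_dense.backward(self.timing_relu.backward(dt))
            dt = dt.reshape((B,) + self.timing.out_shape)
            self.timing.backward(dt)
        else:
            dm = d
        dcat = self.morph_dense.backward(self.morph_relu.backward(dm))
        n1, _ = self._morph_split
        d1 = dcat[:, :n1].reshape((B * 2,) + self.path1.out_shape)
        d2 = dcat[:, n1:].reshape((B * 2,) + self.path2.out_shape)
        df = self.path1.backward(d1) + self.path2.backward(d2)
        # gradient w.r.t. the morphology input is discarded (inputs are data)
        del df

    def predict_proba(self, morph: np.ndarray, timing: np.ndarray | None) -> np.ndarray:
        return _softmax(self.forward(morph, timing, training=False))


def build_network(cfg: NetworkConfig, seed: int = 0) -> ParallelCNN:
    """Construct an untrained classifier (raises on inconsistent shapes)."""
    return ParallelCNN(cfg, seed=seed)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params: list[tuple[_Layer, Param]]) -> None:
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for layer, p in params:
            if not layer.trainable:
                continue
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / corr1) / (np.sqrt(p.v / corr2) + self.eps)


def _as_arrays(dataset):
    """Accept (morph, timing, y) tuples or dicts with those keys."""
    if isinstance(dataset, dict):
        return dataset["morphology"], dataset.get("timing"), dataset["label"]
    morph, timing, y = dataset
    return morph, timing, np.asarray(y)


def _accuracy(model: ParallelCNN, morph, timing, y, batch: int = 1000) -> float:
    correct = 0
    for lo in range(0, len(y), batch):
        sl = slice(lo, lo + batch)
        t = timing[sl] if timing is not None else None
        probs = model.predict_proba(morph[sl], t)
        correct += int(np.sum(probs.argmax(axis=1) == y[sl]))
    return 100.0 * correct / max(len(y), 1)


def train(model: ParallelCNN, train_set, val_set=None,
          cfg: TrainConfig | None = None) -> ParallelCNN:
    """Mini-batch Adam training with softmax cross-entropy + L2.

    Optionally early-stops when training accuracy has not improved for
    ``early_stop_patience`` epochs.  The per-epoch history (loss, training
    and validation accuracy) is appended to ``model.training_history``.
    """
    cfg = cfg or TrainConfig()
    morph, timing, y = _as_arrays(train_set)
    y = np.asarray(y, dtype=int)
    present = set(np.unique(y).tolist())
    if len(present) < model.config.n_classes:
        import warnings

        warnings.warn("not every class is present in the training set; "
                      "metrics for absent classes will be undefined", stacklevel=2)
    params = model.parameters()
    opt = _Adam(cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    lam = model.config.l2_lambda
    n = len(y)
    best_acc, since_best = -1.0, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo: lo + cfg.batch_size]
            mb = np.asarray(morph[sel], dtype=float)
            tb = np.asarray(timing[sel], dtype=float) if timing is not None else None
            yb = y[sel]
            logits = model.forward(mb, tb, training=True)
            probs = _softmax(logits)
            ce = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            if lam > 0:
                ce += lam * sum(float(np.sum(p.value ** 2))
                                for _, p in params if p.l2)
            total_loss += ce * len(yb)
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            for _, p in params:
                p.grad[...] = 0.0
            model.backward(dlogits)
            if lam > 0:
                for layer, p in params:
                    if p.l2 and layer.trainable:
                        p.grad += 2.0 * lam * p.value
            opt.step(params)
        train_acc = 100.0 * correct / n
        entry = {"epoch": epoch, "loss": total_loss / n, "train_accuracy": train_acc}
        if val_set is not None:
            vm, vt, vy = _as_arrays(val_set)
            entry["val_accuracy"] = _accuracy(model, vm, vt, np.asarray(vy, dtype=int))
        model.training_history.append(entry)
        if cfg.early_stop_patience is not None:
            if train_acc > best_acc + 1e-9:
                best_acc, since_best = train_acc, 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
    return model


def transfer(model: ParallelCNN, target_train, target_val=None,
             mode: str = "full_finetune",
             cfg: TrainConfig | None = None) -> ParallelCNN:
    """Fine-tune a pre-trained model on a target dataset.

    ``full_finetune`` updates every weight from the source initialization;
    ``freeze_features`` freezes all convolutional/batch-norm layers (weights
    and statistics stay bit-identical) and retrains only the dense layers.
    """
    if mode not in ("full_finetune", "freeze_features"):
        raise ValueError(f"unknown transfer mode {mode!r}")
    if mode == "freeze_features":
        model.set_feature_layers_trainable(False)
    try:
        train(model, target_train, target_val, cfg)
    finally:
        if mode == "freeze_features":
            model.set_feature_layers_trainable(True)
    model.provenance["transfer_mode"] = mode
    return model


def _split_inputs(inputs):
    if isinstance(inputs, dict):
        return inputs["morphology"], inputs.get("timing")
    if len(inputs) == 3:
        morph, timing, _ = inputs
        return morph, timing
    morph, timing = inputs
    return morph, timing


def predict(model: ParallelCNN, inputs):
    """Per-input probability vectors and argmax labels (deterministic:
    dropout off, batch-norm in inference mode)."""
    morph, timing = _split_inputs(inputs)
    probs = model.predict_proba(morph, timing)
    return probs, probs.argmax(axis=1)


def ensemble_predict(models: list[ParallelCNN], inputs) -> np.ndarray:
    """Majority vote over models; ties go to the label with the highest mean
    softmax probability among the tied labels."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    morph, timing = _split_inputs(inputs)
    all_probs = np.stack([m.predict_proba(morph, timing) for m in models])
    votes = all_probs.argmax(axis=2)  # (n_models, n_inputs)
    n_classes = all_probs.shape[2]
    counts = np.zeros((votes.shape[1], n_classes), dtype=int)
    for k in range(n_classes):
        counts[:, k] = np.sum(votes == k, axis=0)
    mean_probs = all_probs.mean(axis=0)
    top = counts.max(axis=1, keepdims=True)
    tied = counts == top
    # rank tied labels by mean probability, everything else at -inf
    scored = np.where(tied, mean_probs, -np.inf)
    return scored.argmax(axis=1)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: ParallelCNN, path) -> None:
    """Single-file checkpoint: config JSON + ordered weight arrays."""
    cfg = asdict(model.config)
    arrays = {}
    for i, (_, p) in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.value
    for i, ly in enumerate(model._conv_layers()):
        if isinstance(ly, BatchNorm1D):
            arrays[f"bn{i}_mean"] = ly.running_mean
            arrays[f"bn{i}_var"] = ly.running_var
    meta = json.dumps({"config": cfg, "seed": model.seed,
                       "provenance": model.provenance})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def _config_from_dict(d: dict) -> NetworkConfig:
    for key in ("morph_path_1", "morph_path_2", "timing_path"):
        d[key] = tuple(ConvBlockSpec(**b) for b in d[key])
    return NetworkConfig(**d)


def load_model(path) -> ParallelCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = ParallelCNN(_config_from_dict(meta["config"]), seed=meta["seed"])
        model.provenance = meta["provenance"]
        for i, (_, p) in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        for i, ly in enumerate(model._conv_layers()):
            if isinstance(ly, BatchNorm1D):
                ly.running_mean[...] = data[f"bn{i}_mean"]
                ly.running_var[...] = data[f"bn{i}_var"]
    return model
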