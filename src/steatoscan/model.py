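"""The shallow-wide CNN, its differential skip connection, and exact complexity accounting.

Architecture (default): a 28x28x1 gray patch passes through

    conv 3x3x64 (stride 1, pad 1) -> ReLU -> maxpool 2x2 (stride 1)
    [+ skip: the input patch, pooled by the same 2x2/stride-1 window,
       broadcast-added across the 64 channels]
    -> conv 3x3x198 (stride 1, no pad) -> ReLU -> flatten (25*25*198 = 123,750)
    -> FC-19200 -> FC-4 -> softmax

The network is deliberately shallow and wide: speckle texture is a low-level
cue that deeper stacks wash out, so width (198 filters) substitutes for
depth, and the skip connection re-injects the pooled input so gray-level
detail lost to convolution reaches the second stage.  During training the
inputs include differential patches, so the skip carries differential content
for exactly those samples.

Complexity is audited exactly (integer parameter and multiply-accumulate
counts per layer, 1 MAC = 1 FLOP, biases/activations/pooling excluded); for
the default architecture the two fully connected layers dominate both totals
(> 99.9%).  The full-width default network is far too large to instantiate
economically (2.38e9 parameters), which is precisely what the audit exposes;
training experiments therefore use :func:`experiment_spec`, a width-scaled
variant with identical topology and skip semantics.

Everything here is plain NumPy: layers implement ``forward``/``backward``
with cached activations, and :class:`ModelState` wires them into a seeded,
deterministic network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError, ShapeError

logger = logging.getLogger(__name__)

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# Architecture specification and shape propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    kernel: int
    filters: int
    stride: int = 1
    padding: int = 0
    type: str = field(default="conv", init=False)


@dataclass(frozen=True)
class ReluSpec:
    type: str = field(default="relu", init=False)


@dataclass(frozen=True)
class PoolSpec:
    window: int = 2
    stride: int = 1
    type: str = field(default="pool", init=False)


@dataclass(frozen=True)
class BatchNormSpec:
    type: str = field(default="batchnorm", init=False)


@dataclass(frozen=True)
class FlattenSpec:
    type: str = field(default="flatten", init=False)


@dataclass(frozen=True)
class FCSpec:
    units: int
    type: str = field(default="fc", init=False)


LayerSpec = ConvSpec | ReluSpec | PoolSpec | BatchNormSpec | FlattenSpec | FCSpec


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptors plus the input shape and skip flag.

    ``input_shape`` is (height, width, channels).  When ``skip_enabled`` the
    single-channel input, downsampled by the first pooling layer's window,
    is broadcast-added to that pooling layer's output (the input of the
    second convolution).
    """

    input_shape: tuple[int, int, int] = (28, 28, 1)
    layers: tuple[LayerSpec, ...] = ()
    skip_enabled: bool = False

    @property
    def class_count(self) -> int:
        for layer in reversed(self.layers):
            if isinstance(layer, FCSpec):
                return layer.units
        raise ShapeError("spec has no fully connected output layer")


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[int, ...]]:
    """Output shape after each layer; raises ShapeError naming the bad layer.

    Conv/pool extent: floor((in + 2*pad - kernel)/stride) + 1, required > 0.
    """
    shapes: list[tuple[int, ...]] = []
    cur: tuple[int, ...] = spec.input_shape
    for i, layer in enumerate(spec.layers):
        name = f"layer {i} ({layer.type})"
        if isinstance(layer, ConvSpec):
            if len(cur) != 3:
                raise ShapeError(f"{name}: expects a 3-D input, got {cur}")
            h, w, _ = cur
            oh = (h + 2 * layer.padding - layer.kernel) // layer.stride + 1
            ow = (w + 2 * layer.padding - layer.kernel) // layer.stride + 1
            if oh < 1 or ow < 1:
                raise ShapeError(f"{name}: output extent {oh}x{ow} not positive")
            cur = (oh, ow, layer.filters)
        elif isinstance(layer, PoolSpec):
            if len(cur) != 3:
                raise ShapeError(f"{name}: expects a 3-D input, got {cur}")
            h, w, c = cur
            oh = (h - layer.window) // layer.stride + 1
            ow = (w - layer.window) // layer.stride + 1
            if h < layer.window or w < layer.window or oh < 1 or ow < 1:
                raise ShapeError(f"{name}: window {layer.window} larger than input {h}x{w}")
            cur = (oh, ow, c)
        elif isinstance(layer, FlattenSpec):
            cur = (int(np.prod(cur)),)
        elif isinstance(layer, FCSpec):
            if len(cur) != 1:
                raise ShapeError(f"{name}: expects a flattened input, got {cur}")
            cur = (layer.units,)
        elif isinstance(layer, (ReluSpec, BatchNormSpec)):
            pass
        else:  # pragma: no cover - exhaustive over LayerSpec
            raise ShapeError(f"{name}: unknown layer type")
        shapes.append(cur)

    if spec.skip_enabled:
        pools = [(i, l) for i, l in enumerate(spec.layers) if isinstance(l, PoolSpec)]
        if not pools:
            raise ShapeError("skip_enabled requires a pooling layer to define the skip path")
        i, pool = pools[0]
        h, w, _ = spec.input_shape
        lam_h = (h - pool.window) // pool.stride + 1
        lam_w = (w - pool.window) // pool.stride + 1
        out_h, out_w = shapes[i][:2]
        if (lam_h, lam_w) != (out_h, out_w):
            raise ShapeError(
                f"skip addend {lam_h}x{lam_w} does not match pool output {out_h}x{out_w}"
            )
    return shapes


def reference_spec(skip_enabled: bool = True, batchnorm: bool = False) -> ArchitectureSpec:
    """The full-width default architecture (28x28 input, 64/198 filters, FC-19200)."""
    layers: list[LayerSpec] = [ConvSpec(kernel=3, filters=64, stride=1, padding=1)]
    if batchnorm:
        layers.append(BatchNormSpec())
    layers += [ReluSpec(), PoolSpec(window=2, stride=1),
               ConvSpec(kernel=3, filters=198, stride=1, padding=0)]
    if batchnorm:
        layers.append(BatchNormSpec())
    layers += [ReluSpec(), FlattenSpec(), FCSpec(units=19200), FCSpec(units=4)]
    return ArchitectureSpec(input_shape=(28, 28, 1), layers=tuple(layers),
                            skip_enabled=skip_enabled)


def experiment_spec(
    window: int = 28,
    conv_filters: tuple[int, ...] = (16, 32),
    kernel: int = 3,
    hidden_units: int = 64,
    skip_enabled: bool = True,
    batchnorm: bool = False,
    class_count: int = 4,
) -> ArchitectureSpec:
    """Width-scaled twin of the default topology, sized for CPU training.

    Same layer order and skip semantics as :func:`reference_spec`: the first
    convolution pads to preserve the extent, a 2x2/stride-1 pool follows,
    then one hidden FC layer and the 4-way head.  Later convolutions are
    padded by ``(kernel - 3) // 2`` so a 3x3 kernel is unpadded (the
    reference topology) while larger kernels in an ablation sweep keep the
    same output extent and hence compare equal-width classifiers.
    """
    layers: list[LayerSpec] = []
    for j, f in enumerate(conv_filters):
        pad = kernel // 2 if j == 0 else max(0, (kernel - 3) // 2)
        layers.append(ConvSpec(kernel=kernel, filters=f, stride=1, padding=pad))
        if batchnorm:
            layers.append(BatchNormSpec())
        layers.append(ReluSpec())
        if j == 0:
            layers.append(PoolSpec(window=2, stride=1))
    layers += [FlattenSpec(), FCSpec(units=hidden_units), FCSpec(units=class_count)]
    return ArchitectureSpec(input_shape=(window, window, 1), layers=tuple(layers),
                            skip_enabled=skip_enabled)


# --- YAML round-trip --------------------------------------------------------

_SPEC_CLASSES = {
    "conv": ConvSpec, "relu": ReluSpec, "pool": PoolSpec,
    "batchnorm": BatchNormSpec, "flatten": FlattenSpec, "fc": FCSpec,
}


def spec_to_yaml(spec: ArchitectureSpec) -> str:
    layers = []
    for layer in spec.layers:
        d = {"type": layer.type}
        for key in ("kernel", "filters", "stride", "padding", "window", "units"):
            if hasattr(layer, key):
                d[key] = getattr(layer, key)
        layers.append(d)
    doc = {
        "input_shape": list(spec.input_shape),
        "skip_enabled": spec.skip_enabled,
        "layers": layers,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> ArchitectureSpec:
    doc = yaml.safe_load(text)
    layers = []
    for d in doc["layers"]:
        cls = _SPEC_CLASSES[d["type"]]
        kwargs = {k: v for k, v in d.items() if k != "type"}
        layers.append(cls(**kwargs))
    return ArchitectureSpec(
        input_shape=tuple(doc["input_shape"]),
        layers=tuple(layers),
        skip_enabled=bool(doc.get("skip_enabled", False)),
    )


# ---------------------------------------------------------------------------
# Exact complexity accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComplexity:
    """Per-layer and total parameter and multiply-accumulate ledger.

    Counts are exact integers.  Convention: conv params = k*k*c_in*f + f,
    fc params = d_in*d_out + d_out, batchnorm params = 2*channels; conv MACs =
    out_h*out_w*f*k*k*c_in, fc MACs = d_in*d_out; biases, activations,
    pooling, normalisation and the skip addition contribute no MACs.
    Millions are reported by rounding half-up.
    """

    per_layer: tuple[dict, ...]
    total_params: int
    total_flops: int
    fc_params: int
    fc_flops: int

    @property
    def params_millions(self) -> int:
        return _round_millions(self.total_params)

    @property
    def flops_millions(self) -> int:
        return _round_millions(self.total_flops)

    @property
    def fc_share_params(self) -> float:
        """Percentage of parameters in fully connected layers."""
        return 100.0 * self.fc_params / self.total_params if self.total_params else 0.0

    @property
    def fc_share_flops(self) -> float:
        return 100.0 * self.fc_flops / self.total_flops if self.total_flops else 0.0

    def to_dict(self) -> dict:
        return {
            "per_layer": list(self.per_layer),
            "total_params": self.total_params,
            "total_flops": self.total_flops,
            "params_millions": self.params_millions,
            "flops_millions": self.flops_millions,
            "fc_share_params_pct": self.fc_share_params,
            "fc_share_flops_pct": self.fc_share_flops,
        }


def _round_millions(x: int) -> int:
    return int(math.floor(x / 1e6 + 0.5))


def _complexity(spec: ArchitectureSpec) -> ModelComplexity:
    rows: list[dict] = []
    cur: tuple[int, ...] = spec.input_shape
    shapes = propagate_shapes(spec)
    in_channels = spec.input_shape[2]
    for i, (layer, out_shape) in enumerate(zip(spec.layers, shapes)):
        params = macs = 0
        if isinstance(layer, ConvSpec):
            params = layer.kernel * layer.kernel * in_channels * layer.filters + layer.filters
            oh, ow, f = out_shape
            macs = oh * ow * f * layer.kernel * layer.kernel * in_channels
            in_channels = layer.filters
        elif isinstance(layer, FCSpec):
            d_in = cur[0]
            params = d_in * layer.units + layer.units
            macs = d_in * layer.units
        elif isinstance(layer, BatchNormSpec):
            params = 2 * (cur[2] if len(cur) == 3 else cur[0])
        rows.append(
            {
                "layer": i,
                "type": layer.type,
                "out_shape": list(out_shape),
                "params": int(params),
                "macs": int(macs),
            }
        )
        cur = out_shape
    total_params = sum(r["params"] for r in rows)
    total_flops = sum(r["macs"] for r in rows)
    fc_params = sum(r["params"] for r in rows if r["type"] == "fc")
    fc_flops = sum(r["macs"] for r in rows if r["type"] == "fc")
    return ModelComplexity(
        per_layer=tuple(rows),
        total_params=total_params,
        total_flops=total_flops,
        fc_params=fc_params,
        fc_flops=fc_flops,
    )


def count_params(spec: ArchitectureSpec) -> ModelComplexity:
    """Exact trainable-parameter ledger for ``spec`` (see ModelComplexity)."""
    return _complexity(spec)


def count_flops(spec: ArchitectureSpec) -> ModelComplexity:
    """Exact forward multiply-accumulate ledger for ``spec`` (1 MAC = 1 FLOP)."""
    return _complexity(spec)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def relu(h: np.ndarray) -> np.ndarray:
    """Rectified linear unit, elementwise max(0, h)."""
    return np.maximum(0, h)


def softmax_head(logits: np.ndarray) -> np.ndarray:
    """Softmax probabilities Y_i = exp(y_i) / sum_k exp(y_k).

    Stabilised by max-subtraction (the softmax is invariant under adding a
    constant to every logit).  Raises on non-finite logits.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ParameterError("softmax received non-finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(r_onehot: np.ndarray, probs: np.ndarray, eps: float = 1e-12) -> float:
    """Cross-entropy L = -sum_i R_i log Y_i (natural log) for one sample.

    A zero probability at the true class is clamped to ``eps`` with a logged
    warning rather than producing an infinite loss.
    """
    r = np.asarray(r_onehot, dtype=np.float64)
    y = np.asarray(probs, dtype=np.float64)
    if r.shape != y.shape:
        raise ShapeError(f"label shape {r.shape} != probability shape {y.shape}")
    y_true = float((r * y).sum())
    if y_true <= 0.0:
        logger.warning("true-class probability %g clamped to %g", y_true, eps)
        y_true = eps
    return -math.log(y_true)


def skip_add(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Add the single-channel skip addend to every channel of ``x``.

    ``x`` has shape (..., H, W, C); ``lam`` has shape (..., H, W) or
    (..., H, W, 1) and must match ``x`` spatially.
    """
    x = np.asarray(x)
    lam = np.asarray(lam)
    if lam.ndim == x.ndim - 1:
        lam = lam[..., None]
    if lam.shape[-1] != 1:
        raise ShapeError(f"skip addend must be single-channel, got {lam.shape}")
    if lam.shape[:-1] != x.shape[:-1]:
        raise ShapeError(f"skip addend {lam.shape} does not match feature map {x.shape}")
    return x + lam


# ---------------------------------------------------------------------------
# NumPy layers (forward + backward with cached activations)
# ---------------------------------------------------------------------------

class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class _Conv(_Layer):
    def __init__(self, spec: ConvSpec, in_channels: int, rng: np.random.Generator):
        self.spec = spec
        k, f = spec.kernel, spec.filters
        fan_in = k * k * in_channels
        self.w = (rng.standard_normal((k, k, in_channels, f)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.b = np.zeros(f, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.spec.kernel, self.spec.stride, self.spec.padding
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        n, h, w, c = x.shape
        cols = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]  # (n,oh,ow,c,k,k)
        oh, ow = cols.shape[1], cols.shape[2]
        cols = np.moveaxis(cols, 3, 5).reshape(n * oh * ow, k * k * c)
        wmat = self.w.reshape(k * k * c, -1)
        out = cols @ wmat + self.b
        if train:
            self._cache = (cols, (n, h, w, c), (oh, ow))
        return out.reshape(n, oh, ow, -1)

    def backward(self, d: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c), (oh, ow) = self._cache
        k, s, p = self.spec.kernel, self.spec.stride, self.spec.padding
        f = self.spec.filters
        d2 = d.reshape(n * oh * ow, f).astype(_DTYPE)
        self.dw = (cols.T @ d2).reshape(self.w.shape)
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.w.reshape(-1, f).T).reshape(n, oh, ow, k, k, c)
        dxp = np.zeros((n, h, w, c), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + oh * s : s, j : j + ow * s : s, :] += dcols[:, :, :, i, j, :]
        self._cache = None
        return dxp[:, p : h - p, p : w - p, :] if p else dxp

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class _Relu(_Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(0, x)

    def backward(self, d):
        out = d * self._mask
        self._mask = None
        return out


class _MaxPool(_Layer):
    def __init__(self, spec: PoolSpec):
        self.spec = spec

    def forward(self, x, train):
        k, s = self.spec.window, self.spec.stride
        n, h, w, c = x.shape
        view = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]  # (n,oh,ow,c,k,k)
        oh, ow = view.shape[1], view.shape[2]
        flat = view.reshape(n, oh, ow, c, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, (n, h, w, c), (oh, ow))
        return out

    def backward(self, d):
        arg, (n, h, w, c), (oh, ow) = self._cache
        k, s = self.spec.window, self.spec.stride
        dx = np.zeros((n, h, w, c), dtype=_DTYPE)
        # route each output gradient to its argmax cell via k*k masked adds
        # (overlapping stride-1 windows forbid a single scatter into a view)
        for i in range(k):
            for j in range(k):
                mask = arg == i * k + j
                dx[:, i : i + oh * s : s, j : j + ow * s : s, :] += d * mask
        self._cache = None
        return dx


class _BatchNorm(_Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_DTYPE)
        self.beta = np.zeros(channels, dtype=_DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(_DTYPE), axes, x.shape)
        return (self.gamma * xhat + self.beta).astype(_DTYPE)

    def backward(self, d):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.dgamma = (d * xhat).sum(axis=axes)
        self.dbeta = d.sum(axis=axes)
        dxhat = d * self.gamma
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(_DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class _FC(_Layer):
    def __init__(self, spec: FCSpec, in_units: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((in_units, spec.units)) * np.sqrt(2.0 / in_units)).astype(_DTYPE)
        self.b = np.zeros(spec.units, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, d):
        d = d.astype(_DTYPE)
        self.dw = self._x.T @ d
        self.db = d.sum(axis=0)
        self._x = None
        return d @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

class ModelState:
    """An instantiated network: seeded weights plus forward/backward machinery.

    The skip path (when enabled) pools the raw single-channel input with the
    first pooling layer's window and adds it to that layer's output; the
    addend carries no trainable parameters, so backpropagation through it is
    the identity on the main path.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        propagate_shapes(spec)  # raises ShapeError with the offending layer
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        self._skip_index: int | None = None
        cur = spec.input_shape
        for i, lspec in enumerate(spec.layers):
            if isinstance(lspec, ConvSpec):
                self.layers.append(_Conv(lspec, cur[2], rng))
                oh = (cur[0] + 2 * lspec.padding - lspec.kernel) // lspec.stride + 1
                ow = (cur[1] + 2 * lspec.padding - lspec.kernel) // lspec.stride + 1
                cur = (oh, ow, lspec.filters)
            elif isinstance(lspec, PoolSpec):
                self.layers.append(_MaxPool(lspec))
                oh = (cur[0] - lspec.window) // lspec.stride + 1
                ow = (cur[1] - lspec.window) // lspec.stride + 1
                cur = (oh, ow, cur[2])
                if spec.skip_enabled and self._skip_index is None:
                    self._skip_index = i
                    self._skip_pool = _MaxPool(lspec)
            elif isinstance(lspec, BatchNormSpec):
                self.layers.append(_BatchNorm(cur[2] if len(cur) == 3 else cur[0]))
            elif isinstance(lspec, ReluSpec):
                self.layers.append(_Relu())
            elif isinstance(lspec, FlattenSpec):
                self.layers.append(_Flatten())
                cur = (int(np.prod(cur)),)
            elif isinstance(lspec, FCSpec):
                self.layers.append(_FC(lspec, cur[0], rng))
                cur = (lspec.units,)

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward --------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch forward pass; ``x`` is (N, H, W, 1) already normalised."""
        h, w, c = self.spec.input_shape
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != (h, w, c):
            raise ShapeError(f"input shape {x.shape[1:]} does not match spec {(h, w, c)}")
        out = x
        for i, layer in enumerate(self.layers):
            out = layer.forward(out, train)
            if self._skip_index is not None and i == self._skip_index:
                lam = self._skip_pool.forward(x[..., :1], train=False)
                out = skip_add(out, lam)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        outs = [
            softmax_head(self.forward_logits(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)


def build_network(spec: ArchitectureSpec, seed: int = 0) -> ModelState:
    """Instantiate ``spec`` with seeded He initialisation (deterministic per seed)."""
    return ModelState(spec, seed=seed)


def normalize_inputs(arrays: Iterable[np.ndarray]) -> np.ndarray:
    """Stack patches and scale gray levels to [0, 1] by dividing by 255.

    Signed differential patches are divided by the same constant, preserving
    their sign and the re-centred class means.
    """
    stacked = np.stack([np.asarray(a, dtype=np.float32) for a in arrays])
    return stacked / np.float32(255.0)


def forward(model: ModelState, patch) -> np.ndarray:
    """Class probabilities for one patch (a Patch, DifferentialPatch or array)."""
    pixels = getattr(patch, "pixels", patch)
    x = normalize_inputs([pixels])
    return model.predict_proba(x)[0]


def save_model(model: ModelState, path) -> None:
    """Checkpoint weights together with the spec YAML and the build seed."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, spec_yaml=spec_to_yaml(model.spec), seed=model.seed, **arrays)


def load_model(path) -> ModelState:
    with np.load(path, allow_pickle=False) as data:
        spec = spec_from_yaml(str(data["spec_yaml"]))
        model = ModelState(spec, seed=int(data["seed"]))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"]
    return model
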