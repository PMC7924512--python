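"""The hybrid 1D-CNN + MLP architecture, with analytic shape accounting.

Morphological branch (input: one 200-sample beat, 1 channel):

    conv(k=11, 16 filters, stride 3) -> BN -> ReLU -> maxpool(3, s=2)
    conv(k=5,  32 filters, stride 1) -> BN -> ReLU -> maxpool(3, s=2)
    conv(k=3,  64 filters, stride 1) -> BN -> ReLU -> maxpool(3, s=2)
    flatten (320)

Head: the 320 flattened morphological features are concatenated with the 4
RR features (324) and passed through a 64-unit ReLU hidden layer and a
4-way softmax output, one unit per AAMI class (N, SVEB, VEB, F).  All conv
and pool layers are un-padded ("valid"), so the length trace is
200 -> 64 -> 31 -> 27 -> 13 -> 11 -> 5 and the parameter budget is 30,276
trainable plus 224 non-trainable (batch-norm running statistics).

The model is implemented directly in NumPy — forward, backward and Adam
live in this package — so the architecture accounting above is backed by
the very arrays being trained.  Gradients are validated against numerical
differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "conv_output_length",
    "count_parameters",
    "build_model",
    "HybridNet",
    "SEGMENT_LENGTH",
    "RR_DIM",
    "N_CLASSES",
]

SEGMENT_LENGTH = 200
RR_DIM = 4
N_CLASSES = 4

BN_EPS = 1e-3       # batch-norm variance floor
BN_MOMENTUM = 0.9   # running-statistics update: run = m*run + (1-m)*batch


@dataclass(frozen=True)
class LayerSpec:
    """One layer: kind plus whichever hyperparameters that kind uses."""

    kind: str  # conv1d | batch_norm | relu | max_pool | flatten | concat | dense
    kernel_size: int | None = None
    n_filters: int | None = None
    stride: int | None = None
    units: int | None = None

    def __post_init__(self) -> None:
        kinds = ("conv1d", "batch_norm", "relu", "max_pool", "flatten", "concat", "dense")
        if self.kind not in kinds:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and not (
            self.kernel_size and self.n_filters and self.stride
        ):
            raise ValueError("conv1d needs kernel_size, n_filters and stride")
        if self.kind == "max_pool" and not (self.kernel_size and self.stride):
            raise ValueError("max_pool needs kernel_size and stride")
        if self.kind == "dense" and not self.units:
            raise ValueError("dense needs units")


def _default_morph_layers() -> tuple[LayerSpec, ...]:
    layers: list[LayerSpec] = []
    for kernel, filters, stride in ((11, 16, 3), (5, 32, 1), (3, 64, 1)):
        layers += [
            LayerSpec("conv1d", kernel_size=kernel, n_filters=filters, stride=stride),
            LayerSpec("batch_norm"),
            LayerSpec("relu"),
            LayerSpec("max_pool", kernel_size=3, stride=2),
        ]
    layers.append(LayerSpec("flatten"))
    return tuple(layers)


def _default_head_layers() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("concat"),
        LayerSpec("dense", units=64),
        LayerSpec("dense", units=N_CLASSES),
    )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Morphological branch + concatenation head, with analytic accounting."""

    input_length: int = SEGMENT_LENGTH
    rr_input_dim: int = RR_DIM
    morph_layers: tuple[LayerSpec, ...] = field(default_factory=_default_morph_layers)
    head_layers: tuple[LayerSpec, ...] = field(default_factory=_default_head_layers)

    def shape_trace(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes, e.g. ('conv1d', (64, 16)) ... ('dense', (4,))."""
        trace: list[tuple[str, tuple[int, ...]]] = []
        length, channels = self.input_length, 1
        for layer in self.morph_layers:
            if layer.kind == "conv1d":
                length = conv_output_length(length, layer.kernel_size, layer.stride)
                channels = layer.n_filters
                shape: tuple[int, ...] = (length, channels)
            elif layer.kind == "max_pool":
                length = conv_output_length(length, layer.kernel_size, layer.stride)
                shape = (length, channels)
            elif layer.kind in ("batch_norm", "relu"):
                shape = (length, channels)
            elif layer.kind == "flatten":
                shape = (length * channels,)
            else:
                raise ValueError(f"{layer.kind} not valid in the morphological branch")
            trace.append((layer.kind, shape))
        width = trace[-1][1][0]
        for layer in self.head_layers:
            if layer.kind == "concat":
                width += self.rr_input_dim
            elif layer.kind == "dense":
                width = layer.units
            else:
                raise ValueError(f"{layer.kind} not valid in the head")
            trace.append((layer.kind, (width,)))
        return trace


def conv_output_length(in_len: int, kernel: int, stride: int) -> int:
    """Un-padded ("valid") output length: floor((in_len - kernel)/stride) + 1."""
    if in_len < kernel:
        raise ValueError(f"input length {in_len} shorter than kernel {kernel}")
    if kernel < 1 or stride < 1:
        raise ValueError("kernel and stride must be positive")
    return (in_len - kernel) // stride + 1


def count_parameters(spec: ArchitectureSpec) -> list[dict]:
    """Per-layer parameter table: name, output shape, trainable, non-trainable.

    conv: kernel*in_channels*filters + filters biases; batch-norm: 2*channels
    trainable (scale, shift) and 2*channels non-trainable (running mean,
    variance); dense: in_dim*units + units; everything else: zero.
    """
    rows: list[dict] = []
    in_channels = 1
    in_width: int | None = None
    for i, (layer, (kind, shape)) in enumerate(
        zip(spec.morph_layers + spec.head_layers, spec.shape_trace())
    ):
        trainable = non_trainable = 0
        if kind == "conv1d":
            trainable = layer.kernel_size * in_channels * layer.n_filters + layer.n_filters
            in_channels = layer.n_filters
        elif kind == "batch_norm":
            trainable = 2 * in_channels
            non_trainable = 2 * in_channels
        elif kind == "dense":
            if in_width is None:
                raise ValueError(f"layer {i}: dense before a flat input")
            trainable = in_width * layer.units + layer.units
        if len(shape) == 1:
            in_width = shape[0]
        rows.append(
            {
                "layer": kind,
                "output_shape": shape,
                "trainable": trainable,
                "non_trainable": non_trainable,
            }
        )
    return rows


def summarize_architecture(spec: ArchitectureSpec) -> str:
    """Text table of the layer stack (for logging / diffing)."""
    rows = count_parameters(spec)
    lines = [f"{'layer':<12}{'output shape':<16}{'trainable':>10}{'non-trainable':>15}"]
    for r in rows:
        shape = " x ".join(str(s) for s in r["output_shape"])
        lines.append(
            f"{r['layer']:<12}{shape:<16}{r['trainable']:>10}{r['non_trainable']:>15}"
        )
    tr = sum(r["trainable"] for r in rows)
    nt = sum(r["non_trainable"] for r in rows)
    lines.append(f"{'total':<12}{'':<16}{tr:>10}{nt:>15}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# NumPy layers (forward + backward)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _conv1d_forward(x, W, b, stride):
    # x: (B, L, Cin); W: (k, Cin, Cout)
    k = W.shape[0]
    win = sliding_window_view(x, k, axis=1)[:, ::stride]  # (B, Lout, Cin, k)
    out = np.einsum("blck,kco->blo", win, W, optimize=True) + b
    return out


def _conv1d_backward(dout, x, W, stride):
    k, _, _ = W.shape
    l_out = dout.shape[1]
    dW = np.empty_like(W)
    dx = np.zeros_like(x)
    db = dout.sum(axis=(0, 1))
    for u in range(k):
        xs = x[:, u : u + stride * l_out : stride]  # (B, Lout, Cin)
        dW[u] = np.einsum("blc,blo->co", xs, dout, optimize=True)
        dx[:, u : u + stride * l_out : stride] += np.einsum(
            "blo,co->blc", dout, W[u], optimize=True
        )
    return dx, dW, db


def _maxpool_forward(x, k, stride):
    win = sliding_window_view(x, k, axis=1)[:, ::stride]  # (B, Lout, C, k)
    out = win.max(axis=-1)
    arg = win.argmax(axis=-1)  # offsets within window
    return out, arg


def _maxpool_backward(dout, arg, in_shape, stride):
    B, L, C = in_shape
    l_out = dout.shape[1]
    dx = np.zeros(in_shape)
    pos = arg + stride * np.arange(l_out)[None, :, None]  # absolute sample index
    b_idx = np.arange(B)[:, None, None]
    c_idx = np.arange(C)[None, None, :]
    np.add.at(dx, (b_idx, pos, c_idx), dout)  # windows overlap (k > stride)
    return dx


class HybridNet:
    """Trainable NumPy implementation of the hybrid architecture.

    Parameters live in ``self.params`` (dict of arrays); batch-norm running
    statistics in ``self.stats``.  ``forward`` in training mode returns a
    cache consumed by ``backward``, which produces gradients keyed like the
    parameters.  Only the default layer stack of :class:`ArchitectureSpec`
    is supported (three conv blocks, one hidden dense, softmax output).
    """

    #: parameter keys holding weight kernels (targets of the l2 penalty)
    KERNEL_KEYS = ("W1", "W2", "W3", "W4", "W5")

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        convs = [l for l in spec.morph_layers if l.kind == "conv1d"]
        if len(convs) != 3 or len([l for l in spec.head_layers if l.kind == "dense"]) != 2:
            raise ValueError("HybridNet supports the canonical 3-conv/2-dense stack")
        self.conv_layers = convs
        self.pool_layers = [l for l in spec.morph_layers if l.kind == "max_pool"]
        self.dense_layers = [l for l in spec.head_layers if l.kind == "dense"]
        flat_dim = spec.shape_trace()[-len(spec.head_layers) - 1][1][0]
        self.concat_dim = flat_dim + spec.rr_input_dim

        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        in_ch = 1
        for i, conv in enumerate(convs, start=1):
            k, co = conv.kernel_size, conv.n_filters
            p[f"W{i}"] = _glorot(rng, (k, in_ch, co), k * in_ch, k * co)
            p[f"b{i}"] = np.zeros(co)
            p[f"gamma{i}"] = np.ones(co)
            p[f"beta{i}"] = np.zeros(co)
            in_ch = co
        dims = [self.concat_dim, self.dense_layers[0].units, self.dense_layers[1].units]
        for j in range(2):
            p[f"W{4 + j}"] = _glorot(rng, (dims[j], dims[j + 1]), dims[j], dims[j + 1])
            p[f"b{4 + j}"] = np.zeros(dims[j + 1])
        self.params = p
        self.stats = {}
        for i, conv in enumerate(convs, start=1):
            self.stats[f"mean{i}"] = np.zeros(conv.n_filters)
            self.stats[f"var{i}"] = np.ones(conv.n_filters)

    # -- accounting ---------------------------------------------------------

    def num_trainable_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def num_non_trainable_params(self) -> int:
        return int(sum(v.size for v in self.stats.values()))

    # -- forward / backward -------------------------------------------------

    def forward(self, segments, rr, training: bool = False):
        """Run the network; returns (probs, cache).

        ``segments``: (B, 200); ``rr``: (B, 4).  In training mode batch-norm
        uses batch statistics and updates the running ones; in inference
        mode it uses the stored running statistics, so each row's output is
        independent of the rest of the batch.
        """
        segments = np.asarray(segments, dtype=float)
        rr = np.asarray(rr, dtype=float)
        if segments.ndim != 2 or segments.shape[1] != self.spec.input_length:
            raise ValueError(
                f"segments must have shape (batch, {self.spec.input_length}), "
                f"got {segments.shape}"
            )
        if rr.shape != (segments.shape[0], self.spec.rr_input_dim):
            raise ValueError(
                f"rr must have shape ({segments.shape[0]}, "
                f"{self.spec.rr_input_dim}), got {rr.shape}"
            )
        cache: dict = {"training": training}
        x = segments[:, :, None]  # (B, 200, 1)
        for i, (conv, pool) in enumerate(zip(self.conv_layers, self.pool_layers), 1):
            cache[f"x{i}"] = x
            z = _conv1d_forward(x, self.params[f"W{i}"], self.params[f"b{i}"], conv.stride)
            cache[f"z{i}"] = z
            if training:
                mu = z.mean(axis=(0, 1))
                var = z.var(axis=(0, 1))
                self.stats[f"mean{i}"] = (
                    BN_MOMENTUM * self.stats[f"mean{i}"] + (1 - BN_MOMENTUM) * mu
                )
                self.stats[f"var{i}"] = (
                    BN_MOMENTUM * self.stats[f"var{i}"] + (1 - BN_MOMENTUM) * var
                )
            else:
                mu, var = self.stats[f"mean{i}"], self.stats[f"var{i}"]
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            zhat = (z - mu) * inv_std
            a = np.maximum(0.0, self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"])
            cache[f"zhat{i}"], cache[f"inv_std{i}"], cache[f"a{i}"] = zhat, inv_std, a
            x, arg = _maxpool_forward(a, pool.kernel_size, pool.stride)
            cache[f"arg{i}"], cache[f"pooled{i}"] = arg, x
        flat = x.reshape(x.shape[0], -1)
        h_in = np.concatenate([flat, rr], axis=1)
        cache["h_in"] = h_in
        h = np.maximum(0.0, h_in @ self.params["W4"] + self.params["b4"])
        cache["h"] = h
        logits = h @ self.params["W5"] + self.params["b5"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def backward(self, cache, dlogits):
        """Gradients of the loss w.r.t. every trainable parameter.

        ``dlogits`` is dL/d(pre-softmax logits), e.g. from
        :func:`focalbeat.losses.softmax_loss_gradient`.
        """
        g: dict[str, np.ndarray] = {}
        h, h_in = cache["h"], cache["h_in"]
        g["W5"] = h.T @ dlogits
        g["b5"] = dlogits.sum(axis=0)
        dh = (dlogits @ self.params["W5"].T) * (h > 0)
        g["W4"] = h_in.T @ dh
        g["b4"] = dh.sum(axis=0)
        dh_in = dh @ self.params["W4"].T
        flat_dim = self.concat_dim - self.spec.rr_input_dim
        dflat = dh_in[:, :flat_dim]
        dx = dflat.reshape(cache["pooled3"].shape)
        for i in range(3, 0, -1):
            conv, pool = self.conv_layers[i - 1], self.pool_layers[i - 1]
            da = _maxpool_backward(
                dx, cache[f"arg{i}"], cache[f"a{i}"].shape, pool.stride
            )
            da *= cache[f"a{i}"] > 0  # ReLU
            zhat, inv_std = cache[f"zhat{i}"], cache[f"inv_std{i}"]
            g[f"gamma{i}"] = (da * zhat).sum(axis=(0, 1))
            g[f"beta{i}"] = da.sum(axis=(0, 1))
            dzhat = da * self.params[f"gamma{i}"]
            if cache["training"]:
                n = zhat.shape[0] * zhat.shape[1]
                dz = (
                    inv_std
                    / n
                    * (
                        n * dzhat
                        - dzhat.sum(axis=(0, 1))
                        - zhat * (dzhat * zhat).sum(axis=(0, 1))
                    )
                )
            else:
                dz = dzhat * inv_std
            dx, dW, db = _conv1d_backward(dz, cache[f"x{i}"], self.params[f"W{i}"], conv.stride)
            g[f"W{i}"], g[f"b{i}"] = dW, db
        return g

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint parameters + running statistics to an .npz file."""
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays.update({f"stat_{k}": v for k, v in self.stats.items()})
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path, spec: ArchitectureSpec | None = None) -> "HybridNet":
        model = cls(spec or ArchitectureSpec(), seed=0)
        with np.load(Path(path)) as data:
            for k in model.params:
                model.params[k] = data[f"param_{k}"]
            for k in model.stats:
                model.stats[k] = data[f"stat_{k}"]
        return model


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> HybridNet:
    """Construct the jointly trainable CNN+MLP with seeded initialization."""
    return HybridNet(spec or ArchitectureSpec(), seed=seed)
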