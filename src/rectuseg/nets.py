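"""Encoder–decoder segmentation networks (plain, nested-skip, residual).

Three fully convolutional architectures for single-channel ultrasound frames:

* ``plain`` — the classic U-shaped encoder–decoder: double 3x3 convolution
  blocks, 2x2 max-pooling, nearest-neighbour upsampling with a channel-
  reducing convolution, and skip concatenation between mirrored levels;
* ``nested`` — the dense-skip variant: intermediate decoder nodes X[i,j]
  re-aggregate every earlier node at the same resolution together with the
  upsampled node one level below, so skip features are refined progressively;
* ``residual`` — the plain topology with every convolution block replaced by
  an identity-shortcut residual block (projection shortcut + batch norm).

The stack is implemented directly on NumPy arrays (NHWC, float32) with
explicit forward/backward passes recorded on a small tape, which keeps the
whole training loop deterministic on CPU for a fixed seed.  The network head
is a 1x1 convolution producing one logit per pixel; probabilities are the
sigmoid of the logits, so every emitted value lies in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import Frame, ParameterError, ProbMap, ShapeError

__all__ = [
    "NetConfig",
    "SegModel",
    "build_model",
    "predict",
    "predict_batch",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# parameters and elementary layers
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: single input, single output, caches live on the instance."""

    def params(self) -> List[Param]:
        return []

    def buffers(self) -> List[np.ndarray]:
        return []

    def set_buffers(self, arrays: Sequence[np.ndarray]) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded stride-1 convolution, NHWC, kernel (k, k, cin, cout)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int = 3, bias: bool = False):
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = k // 2
        self.W = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._xp: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp if train else None
        y = np.zeros((n * h * w, self.cout), dtype=_F32)
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :])
                y += xs.reshape(-1, self.cin) @ self.W.value[di, dj]
        if self.b is not None:
            y += self.b.value
        return y.reshape(n, h, w, self.cout)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward before training-mode forward"
        n, h, w, _ = g.shape
        p = self.pad
        g2 = np.ascontiguousarray(g).reshape(-1, self.cout)
        dxp = np.zeros_like(self._xp)
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(self._xp[:, di : di + h, dj : dj + w, :])
                self.W.grad[di, dj] += xs.reshape(-1, self.cin).T @ g2
                dxp[:, di : di + h, dj : dj + w, :] += (
                    g2 @ self.W.value[di, dj].T
                ).reshape(n, h, w, self.cin)
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum = momentum
        self.eps = eps
        self._cache: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> List[np.ndarray]:
        return [self.running_mean, self.running_var]

    def set_buffers(self, arrays: Sequence[np.ndarray]) -> None:
        self.running_mean = arrays[0].astype(_F32)
        self.running_var = arrays[1].astype(_F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(_F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd) if train else None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, invstd = self._cache
        axes = (0, 1, 2)
        self.dgamma_dbeta(g, xhat)
        dxhat = g * self.gamma.value
        mean_dxhat = dxhat.mean(axis=axes)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)
        dx = invstd * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx.astype(_F32)

    def dgamma_dbeta(self, g: np.ndarray, xhat: np.ndarray) -> None:
        axes = (0, 1, 2)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        self._mask = mask if train else None
        return np.where(mask, x, 0).astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = np.where(self._mask, g, 0).astype(_F32)
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling; gradient is split evenly among tied maxima."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"grid {h}x{w} not divisible by 2 for pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            mask = xr == y[:, :, None, :, None, :]
            counts = mask.sum(axis=(2, 4), keepdims=True)
            self._cache = (mask, counts, x.shape)
        return np.ascontiguousarray(y, dtype=_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        mask, counts, shape = self._cache
        gexp = (g[:, :, None, :, None, :] / counts) * mask
        self._cache = None
        return gexp.reshape(shape).astype(_F32)


class UpNearest2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(_F32)


# ---------------------------------------------------------------------------
# tape-based graph (concatenation / addition need fan-out bookkeeping)
# ---------------------------------------------------------------------------


class _Graph:
    """Records the forward pass so gradients can flow back through skips."""

    def __init__(self) -> None:
        self.vals: Dict[int, np.ndarray] = {}
        self.tape: List[Tuple] = []
        self._n = 0

    def _new(self, x: np.ndarray) -> int:
        i = self._n
        self._n += 1
        self.vals[i] = x
        return i

    def source(self, x: np.ndarray) -> int:
        return self._new(x)

    def apply(self, layer: Layer, i: int, train: bool) -> int:
        y = layer.forward(self.vals[i], train)
        j = self._new(y)
        self.tape.append(("layer", layer, (i,), j))
        return j

    def concat(self, ids: Sequence[int]) -> int:
        xs = [self.vals[i] for i in ids]
        sizes = [x.shape[-1] for x in xs]
        j = self._new(np.concatenate(xs, axis=-1))
        self.tape.append(("concat", sizes, tuple(ids), j))
        return j

    def add(self, i: int, k: int) -> int:
        j = self._new(self.vals[i] + self.vals[k])
        self.tape.append(("add", None, (i, k), j))
        return j

    def backward(self, out_id: int, g: np.ndarray) -> None:
        grads: Dict[int, np.ndarray] = {out_id: g}
        for kind, payload, in_ids, out in reversed(self.tape):
            go = grads.pop(out, None)
            if go is None:
                continue
            if kind == "layer":
                gi = payload.backward(go)
                self._acc(grads, in_ids[0], gi)
            elif kind == "concat":
                offs = np.cumsum([0] + list(payload))
                for idx, i in enumerate(in_ids):
                    self._acc(grads, i, go[..., offs[idx] : offs[idx + 1]])
            else:  # add
                for i in in_ids:
                    self._acc(grads, i, go)

    @staticmethod
    def _acc(grads: Dict[int, np.ndarray], i: int, g: np.ndarray) -> None:
        if i in grads:
            grads[i] = grads[i] + g
        else:
            grads[i] = g


# ---------------------------------------------------------------------------
# composite blocks
# ---------------------------------------------------------------------------


class _Block:
    def layers(self) -> Iterator[Layer]:  # pragma: no cover
        raise NotImplementedError

    def apply(self, G: _Graph, i: int, train: bool) -> int:  # pragma: no cover
        raise NotImplementedError


class DoubleConv(_Block):
    """conv3x3-BN-ReLU twice — the classic U-shaped network block."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.seq: List[Layer] = [
            Conv2d(rng, cin, cout), BatchNorm2d(cout), ReLU(),
            Conv2d(rng, cout, cout), BatchNorm2d(cout), ReLU(),
        ]

    def layers(self) -> Iterator[Layer]:
        yield from self.seq

    def apply(self, G: _Graph, i: int, train: bool) -> int:
        for lyr in self.seq:
            i = G.apply(lyr, i, train)
        return i


class ResidualBlock(_Block):
    """Two 3x3 convolutions with a projected identity shortcut."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.c1 = Conv2d(rng, cin, cout)
        self.b1 = BatchNorm2d(cout)
        self.r1 = ReLU()
        self.c2 = Conv2d(rng, cout, cout)
        self.b2 = BatchNorm2d(cout)
        self.sc = Conv2d(rng, cin, cout, k=1)
        self.sb = BatchNorm2d(cout)
        self.rout = ReLU()

    def layers(self) -> Iterator[Layer]:
        yield from (self.c1, self.b1, self.r1, self.c2, self.b2,
                    self.sc, self.sb, self.rout)

    def apply(self, G: _Graph, i: int, train: bool) -> int:
        j = G.apply(self.c1, i, train)
        j = G.apply(self.b1, j, train)
        j = G.apply(self.r1, j, train)
        j = G.apply(self.c2, j, train)
        j = G.apply(self.b2, j, train)
        s = G.apply(self.sc, i, train)
        s = G.apply(self.sb, s, train)
        out = G.add(j, s)
        return G.apply(self.rout, out, train)


class UpBlock(_Block):
    """Nearest-neighbour 2x upsampling followed by a channel-reducing conv."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.up = UpNearest2()
        self.conv = Conv2d(rng, cin, cout)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def layers(self) -> Iterator[Layer]:
        yield from (self.conv, self.bn, self.relu)

    def apply(self, G: _Graph, i: int, train: bool) -> int:
        i = G.apply(self.up, i, train)
        i = G.apply(self.conv, i, train)
        i = G.apply(self.bn, i, train)
        return G.apply(self.relu, i, train)


# ---------------------------------------------------------------------------
# configuration and model
# ---------------------------------------------------------------------------

_VARIANTS = ("plain", "nested", "residual")


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``depth`` counts resolution levels (so inputs must be divisible by
    ``2**(depth-1)``); ``base_channels`` is the width at full resolution and
    doubles at every level down.
    """

    variant: str = "residual"
    depth: int = 5
    base_channels: int = 64
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ParameterError(f"variant must be one of {_VARIANTS}")
        if self.depth < 2:
            raise ParameterError("depth must be >= 2")
        if self.base_channels < 1:
            raise ParameterError("base_channels must be >= 1")
        if self.in_channels != 1:
            raise ParameterError("only single-channel input is supported")

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "depth": self.depth,
                "base_channels": self.base_channels,
                "in_channels": self.in_channels,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetConfig":
        return cls(**json.loads(s))


class SegModel:
    """A built segmentation network: blocks wired into a U-shaped graph."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.depth
        ch = [config.base_channels * (2**i) for i in range(d)]
        block = ResidualBlock if config.variant == "residual" else DoubleConv
        self._graph: Optional[_Graph] = None
        self._out_id: Optional[int] = None

        if config.variant in ("plain", "residual"):
            self.enc = [
                block(rng, config.in_channels if i == 0 else ch[i - 1], ch[i])
                for i in range(d)
            ]
            self.pools = [MaxPool2() for _ in range(d - 1)]
            self.ups = [UpBlock(rng, ch[i + 1], ch[i]) for i in range(d - 1)]
            self.dec = [block(rng, 2 * ch[i], ch[i]) for i in range(d - 1)]
            self.nested: Optional[dict] = None
        else:  # nested dense-skip topology
            self.enc = [
                DoubleConv(rng, config.in_channels if i == 0 else ch[i - 1], ch[i])
                for i in range(d)
            ]
            self.pools = [MaxPool2() for _ in range(d - 1)]
            self.nested = {}
            for j in range(1, d):
                for i in range(d - j):
                    up = UpBlock(rng, ch[i + 1], ch[i])
                    node = DoubleConv(rng, (j + 1) * ch[i], ch[i])
                    self.nested[(i, j)] = (up, node)
            self.ups = []
            self.dec = []
        self.head = Conv2d(rng, ch[0], 1, k=1, bias=True)

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> Iterator[Layer]:
        for b in self.enc:
            yield from b.layers()
        for p in self.pools:
            yield p
        if self.nested is not None:
            for j in range(1, self.config.depth):
                for i in range(self.config.depth - j):
                    up, node = self.nested[(i, j)]
                    yield from up.layers()
                    yield from node.layers()
        else:
            for u in self.ups:
                yield from u.layers()
            for b in self.dec:
                yield from b.layers()
        yield self.head

    def parameters(self) -> List[Param]:
        return [p for lyr in self._all_layers() for p in lyr.params()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_arrays(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for lyr in self._all_layers():
            out.extend(p.value for p in lyr.params())
            out.extend(lyr.buffers())
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for lyr in self._all_layers():
            for p in lyr.params():
                p.value = next(it).astype(_F32).reshape(p.value.shape)
                p.grad = np.zeros_like(p.value)
            nbuf = len(lyr.buffers())
            if nbuf:
                lyr.set_buffers([next(it) for _ in range(nbuf)])

    def copy_state(self) -> List[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    # -- forward / backward ------------------------------------------------

    def _check_shape(self, h: int, w: int) -> None:
        div = self.config.divisor
        if h % div or w % div:
            raise ShapeError(
                f"input {h}x{w} not divisible by 2^(depth-1) = {div}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (N, H, W, 1) float batch to per-pixel logits (N, H, W)."""
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 3:
            x = x[..., None]
        n, h, w, _ = x.shape
        self._check_shape(h, w)
        G = _Graph()
        i = G.source(x)
        d = self.config.depth

        if self.nested is None:
            skips = []
            for lvl in range(d):
                i = self.enc[lvl].apply(G, i, train)
                skips.append(i)
                if lvl < d - 1:
                    i = G.apply(self.pools[lvl], i, train)
            for lvl in range(d - 2, -1, -1):
                u = self.ups[lvl].apply(G, i, train)
                i = self.dec[lvl].apply(G, G.concat([skips[lvl], u]), train)
        else:
            X: Dict[Tuple[int, int], int] = {}
            for lvl in range(d):
                i = self.enc[lvl].apply(G, i, train)
                X[(lvl, 0)] = i
                if lvl < d - 1:
                    i = G.apply(self.pools[lvl], i, train)
            for j in range(1, d):
                for lvl in range(d - j):
                    up, node = self.nested[(lvl, j)]
                    u = up.apply(G, X[(lvl + 1, j - 1)], train)
                    cat = G.concat([X[(lvl, jj)] for jj in range(j)] + [u])
                    X[(lvl, j)] = node.apply(G, cat, train)
            i = X[(0, d - 1)]

        out = G.apply(self.head, i, train)
        if train:
            self._graph, self._out_id = G, out
        return G.vals[out][..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits), accumulating parameter grads."""
        assert self._graph is not None and self._out_id is not None
        self._graph.backward(self._out_id, np.asarray(dlogits, dtype=_F32)[..., None])
        self._graph = None
        self._out_id = None


def build_model(config: NetConfig) -> SegModel:
    """Build a seeded model; identical config (incl. seed) gives identical
    initial parameters."""
    return SegModel(config)


def count_parameters(model: SegModel) -> int:
    return int(sum(p.value.size for p in model.parameters()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_batch(model: SegModel, x: np.ndarray) -> np.ndarray:
    """Inference-mode probabilities for a (N, H, W[, 1]) float batch in [0,1]."""
    logits = model.forward(x, train=False)
    return _sigmoid(logits)


def predict(model: SegModel, frame: Frame) -> ProbMap:
    """Per-pixel foreground probability for one frame (no parameter update)."""
    x = frame.pixels.astype(_F32)[None, ...] / 255.0
    probs = predict_batch(model, x)[0]
    return ProbMap(np.clip(probs, 0.0, 1.0), frame.pixel_size_mm)


def save_checkpoint(model: SegModel, path: Union[str, Path]) -> None:
    """Serialize parameters, BN statistics and the config header."""
    arrays = model.state_arrays()
    np.savez(
        Path(path),
        __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
        **{f"arr_{i}": a for i, a in enumerate(arrays)},
    )


def load_checkpoint(path: Union[str, Path]) -> SegModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as z:
        config = NetConfig.from_json(bytes(z["__config__"]).decode())
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model = build_model(config)
    model.load_state_arrays(arrays)
    return model
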