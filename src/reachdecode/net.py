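"""Compact depthwise-separable CNN for epoched-EEG classification.

The architecture is the EEGNet family laid out for (channels C = 60,
samples T) inputs:

====  ==========================  ======================  ==============
blk   layer                       hyper-parameters        output (T=640)
====  ==========================  ======================  ==============
 1    temporal conv               8 filters, length 16    (8, 60, 640)
      batch norm                                          (8, 60, 640)
      depthwise spatial conv      16 filters, length 60   (16, 1, 640)
      batch norm + ELU                                    (16, 1, 640)
      average pool                length 4                (16, 1, 160)
      dropout                     p = 0.1                 (16, 1, 160)
 2    separable temporal conv     16 filters, length 8    (16, 1, 160)
      batch norm + ELU                                    (16, 1, 160)
      average pool                length 4                (16, 1, 40)
      dropout                     p = 0.1                 (16, 1, 40)
 3    flatten                                             640
      fully connected + softmax   n_classes
====  ==========================  ======================  ==============

All convolutions are linear (no activation) and bias-free; batch
normalization follows each convolution.  "Same" zero padding for the
even-length temporal kernels puts the extra pad sample on the trailing
side.  An optional max-norm constraint on the depthwise and dense weights
(present in the architecture's original formulation) is off by default.

Everything is pure NumPy.  Each layer implements ``forward``/``backward``
for training and ``multipliers`` for DeepLIFT relevance propagation
(Rescale rule), so training and attribution share one definition of the
network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyper-parameters; defaults follow the table above."""

    n_channels: int = 60
    n_samples: int = 640
    n_classes: int = 3
    temporal_filters: int = 8
    temporal_length: int = 16
    depth_multiplier: int = 2          # 8 maps x 2 = 16 depthwise filters
    separable_filters: int = 16
    separable_length: int = 8
    pool_length: int = 4
    dropout: float = 0.1
    max_norm: float | None = None      # optional weight constraint, off

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        prod = self.pool_length ** 2
        if self.n_samples % prod:
            raise ValueError(
                f"n_samples={self.n_samples} must be divisible by the pooling "
                f"product {prod}"
            )

    @property
    def spatial_filters(self) -> int:
        return self.temporal_filters * self.depth_multiplier

    @property
    def flat_width(self) -> int:
        return self.separable_filters * (self.n_samples // self.pool_length ** 2)


def _same_pad(k: int) -> tuple[int, int]:
    """'Same' padding for kernel length k; extra sample trails for even k."""
    return (k - 1) // 2, k // 2


def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    """Trailing-axis sliding windows view, shape (..., T, k)."""
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)


class Layer:
    """Interface: forward / backward / DeepLIFT multipliers."""

    train_only = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def multipliers(self, m: np.ndarray, x: np.ndarray, x_ref: np.ndarray,
                    y: np.ndarray, y_ref: np.ndarray) -> np.ndarray:
        """Propagate DeepLIFT multipliers from output to input.

        For purely linear layers this equals the gradient backward pass and
        conserves sum(m_in * (x - x_ref)) == sum(m_out * (y - y_ref)).
        """
        raise NotImplementedError


class TemporalConv(Layer):
    """1-map -> F-map convolution along time, same padding, no bias.

    Input (B, 1, C, T) -> output (B, F, C, T).
    """

    def __init__(self, n_filters: int, length: int, rng: np.random.Generator):
        self.k = length
        limit = np.sqrt(6.0 / (length + n_filters * length))
        self.w = rng.uniform(-limit, limit, (n_filters, length)).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]

    def forward(self, x, training=False):
        pl, pr = _same_pad(self.k)
        xp = np.pad(x[:, 0], ((0, 0), (0, 0), (pl, pr)))
        # materialize im2col once; reused by backward for dW
        cols = np.ascontiguousarray(_sliding(xp, self.k))  # (B, C, T, k)
        self._cols = cols if training else None
        B, C, T, k = cols.shape
        y = cols.reshape(-1, k) @ self.w.T.astype(cols.dtype)  # (BCT, F)
        return np.ascontiguousarray(
            y.reshape(B, C, T, -1).transpose(0, 3, 1, 2))

    def backward(self, g):
        cols, k = self._cols, self.k
        B, C, T, _ = cols.shape
        pl, pr = _same_pad(k)
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))   # (B, C, T, F)
        self.dw += (
            gt.reshape(-1, gt.shape[-1]).T @ cols.reshape(-1, k)
        ).astype(self.w.dtype)
        return self._linear_back(g).astype(g.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        return self._linear_back(m)

    def _linear_back(self, m):
        # dx[t] = sum_{f,k} m[f, t'] w[f, k]: contract filters first (BLAS),
        # then gather the k diagonals by shifted adds
        k = self.k
        pl, pr = _same_pad(k)
        T = m.shape[-1]
        gp = np.pad(m, ((0, 0), (0, 0), (0, 0), (pr, pl)))
        v = np.tensordot(gp, self.w[:, ::-1].astype(m.dtype),
                         axes=([1], [0]))                 # (B, C, Tp, k)
        dx = np.zeros(m.shape[:1] + m.shape[2:], dtype=v.dtype)
        for j in range(k):
            dx += v[:, :, j:j + T, j]
        return dx[:, None]


class DepthwiseSpatialConv(Layer):
    """Per-map spatial filters spanning all channels (valid convolution).

    Input (B, F, C, T) -> output (B, F*D, 1, T); weights (F, D, C).
    """

    def __init__(self, in_maps: int, depth_multiplier: int, n_channels: int,
                 rng: np.random.Generator, max_norm: float | None = None):
        limit = np.sqrt(6.0 / (n_channels + n_channels))
        self.w = rng.uniform(
            -limit, limit, (in_maps, depth_multiplier, n_channels)
        ).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self.max_norm = max_norm

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]

    def constrain(self):
        if self.max_norm is not None:
            norms = np.linalg.norm(self.w, axis=2, keepdims=True)
            factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
            self.w *= factor

    def forward(self, x, training=False):
        self._x = x
        B, F, C, T = x.shape
        # batched GEMM: (F, D, C) @ (B, F, C, T) -> (B, F, D, T)
        y = np.matmul(self.w[None].astype(x.dtype), x)
        return y.reshape(B, -1, 1, T)

    def backward(self, g):
        x = self._x
        B, F, C, T = x.shape
        D = self.w.shape[1]
        gr = g.reshape(B, F, D, T)
        self.dw += np.matmul(gr, x.transpose(0, 1, 3, 2)).sum(axis=0).astype(
            self.w.dtype)
        dx = np.matmul(self.w[None].transpose(0, 1, 3, 2).astype(g.dtype), gr)
        return dx.astype(x.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        B = m.shape[0]
        F, D, C = self.w.shape
        gr = m.reshape(B, F, D, -1)
        return np.matmul(self.w[None].transpose(0, 1, 3, 2).astype(m.dtype), gr)


class SeparableTemporalConv(Layer):
    """Depthwise temporal convolution followed by pointwise map mixing.

    Input (B, M, 1, T) -> output (B, P, 1, T); depthwise weights (M, k),
    pointwise weights (P, M).
    """

    def __init__(self, in_maps: int, out_maps: int, length: int,
                 rng: np.random.Generator):
        self.k = length
        limit_d = np.sqrt(6.0 / (length + length))
        self.wd = rng.uniform(-limit_d, limit_d, (in_maps, length)).astype(
            np.float32)
        limit_p = np.sqrt(6.0 / (in_maps + out_maps))
        self.wp = rng.uniform(-limit_p, limit_p, (out_maps, in_maps)).astype(
            np.float32)
        self.dwd = np.zeros_like(self.wd)
        self.dwp = np.zeros_like(self.wp)

    def params(self):
        return [self.wd, self.wp]

    def grads(self):
        return [self.dwd, self.dwp]

    def _depthwise(self, x2: np.ndarray) -> np.ndarray:
        pl, pr = _same_pad(self.k)
        xp = np.pad(x2, ((0, 0), (0, 0), (pl, pr)))
        cols = _sliding(xp, self.k)                      # (B, M, T, k)
        return np.einsum("bmtk,mk->bmt", cols, self.wd)

    def forward(self, x, training=False):
        self._x2 = x[:, :, 0, :]                          # (B, M, T)
        self._mid = self._depthwise(self._x2)             # (B, M, T)
        y = np.einsum("bmt,pm->bpt", self._mid, self.wp)
        return y[:, :, None, :]

    def backward(self, g):
        g2 = g[:, :, 0, :]                                # (B, P, T)
        self.dwp += np.einsum("bpt,bmt->pm", g2, self._mid).astype(self.wp.dtype)
        gmid = np.einsum("bpt,pm->bmt", g2, self.wp)
        pl, pr = _same_pad(self.k)
        xp = np.pad(self._x2, ((0, 0), (0, 0), (pl, pr)))
        cols = _sliding(xp, self.k)
        self.dwd += np.einsum("bmtk,bmt->mk", cols, gmid).astype(self.wd.dtype)
        gp = np.pad(gmid, ((0, 0), (0, 0), (pr, pl)))
        gcols = _sliding(gp, self.k)
        dx = np.einsum("bmtk,mk->bmt", gcols, self.wd[:, ::-1])
        return dx[:, :, None, :].astype(g.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        g2 = m[:, :, 0, :]
        gmid = np.einsum("bpt,pm->bmt", g2, self.wp)
        pl, pr = _same_pad(self.k)
        gp = np.pad(gmid, ((0, 0), (0, 0), (pr, pl)))
        gcols = _sliding(gp, self.k)
        dx = np.einsum("bmtk,mk->bmt", gcols, self.wd[:, ::-1])
        return dx[:, :, None, :]


class BatchNorm(Layer):
    """Batch normalization over all but the map axis (axis 1)."""

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_maps, dtype=np.float32)
        self.beta = np.zeros(n_maps, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n_maps, dtype=np.float32)
        self.run_var = np.ones(n_maps, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False):
        sh = self._bshape(x)
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            self.run_mean += self.momentum * (mean - self.run_mean)
            unbiased = var * n / max(n - 1, 1)
            self.run_var += self.momentum * (unbiased - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) / self._std.reshape(sh)
        self._training = training
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, g):
        sh = self._bshape(g)
        axes = (0,) + tuple(range(2, g.ndim))
        prod = g * self._xhat
        dgam = prod.sum(axis=axes)
        self.dgamma += dgam.astype(self.gamma.dtype)
        self.dbeta += g.sum(axis=axes).astype(self.beta.dtype)
        gs = (self.gamma / self._std).reshape(sh).astype(g.dtype)
        if not self._training:
            return g * gs
        n = g.size // g.shape[1]
        mean_g = (g.mean(axis=axes)).reshape(sh).astype(g.dtype)
        mean_prod = (dgam / n).reshape(sh).astype(g.dtype)
        return (g - mean_g - self._xhat * mean_prod) * gs

    def multipliers(self, m, x, x_ref, y, y_ref):
        # inference-mode BN is affine; bias terms cancel in deltas
        sh = self._bshape(m)
        scale = (self.gamma / np.sqrt(self.run_var + self.eps)).reshape(sh)
        return m * scale


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._x = x
        self._y = np.where(x > 0, x, self.alpha * np.expm1(x))
        return self._y

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + self.alpha).astype(g.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        # Rescale rule: m = (y - y_ref) / (x - x_ref); gradient at tiny delta
        dx = x - x_ref
        dy = y - y_ref
        grad = np.where(x > 0, 1.0, y + self.alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = dy / dx
        return m * np.where(np.abs(dx) < 1e-7, grad, r)


class AvgPool(Layer):
    """Average pooling along the trailing (time) axis."""

    def __init__(self, length: int):
        self.k = length

    def forward(self, x, training=False):
        B, M, C, T = x.shape
        if T % self.k:
            raise ValueError(f"time length {T} not divisible by pool {self.k}")
        return x.reshape(B, M, C, T // self.k, self.k).mean(axis=-1)

    def backward(self, g):
        return np.repeat(g, self.k, axis=-1) / self.k

    def multipliers(self, m, x, x_ref, y, y_ref):
        return np.repeat(m, self.k, axis=-1) / self.k


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask.astype(g.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        return m  # inference: identity


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def multipliers(self, m, x, x_ref, y, y_ref):
        return m.reshape(x.shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 max_norm: float | None = None):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.max_norm = max_norm

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def constrain(self):
        if self.max_norm is not None:
            norms = np.linalg.norm(self.w, axis=0, keepdims=True)
            self.w *= np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw += (self._x.T @ g).astype(self.w.dtype)
        self.db += g.sum(axis=0).astype(self.b.dtype)
        return (g @ self.w.T).astype(g.dtype)

    def multipliers(self, m, x, x_ref, y, y_ref):
        return m @ self.w.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class EEGDecoder:
    """The full network: layer stack, loss, and DeepLIFT attribution."""

    def __init__(self, spec: NetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.layers: list[Layer] = [
            TemporalConv(s.temporal_filters, s.temporal_length, rng),
            BatchNorm(s.temporal_filters),
            DepthwiseSpatialConv(s.temporal_filters, s.depth_multiplier,
                                 s.n_channels, rng, max_norm=s.max_norm),
            BatchNorm(s.spatial_filters),
            ELU(),
            AvgPool(s.pool_length),
            Dropout(s.dropout, rng),
            SeparableTemporalConv(s.spatial_filters, s.separable_filters,
                                  s.separable_length, rng),
            BatchNorm(s.separable_filters),
            ELU(),
            AvgPool(s.pool_length),
            Dropout(s.dropout, rng),
            Flatten(),
            Dense(s.flat_width, s.n_classes, rng, max_norm=s.max_norm),
        ]

    # -- shape contract -------------------------------------------------
    def shape_trace(self) -> list[tuple[str, tuple[int, ...]]]:
        """Layer-by-layer output shapes for a single input, sans batch axis."""
        x = np.zeros((1, 1, self.spec.n_channels, self.spec.n_samples),
                     dtype=np.float32)
        out = [("input", x.shape[1:])]
        for layer in self.layers:
            x = layer.forward(x, training=False)
            out.append((type(layer).__name__, x.shape[1:]))
        out.append(("softmax", (self.spec.n_classes,)))
        return out

    # -- inference ------------------------------------------------------
    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pre-softmax class scores for (B, C, T) input."""
        h = x[:, None, :, :]
        for layer in self.layers:
            h = layer.forward(h, training=training)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, training=False))

    # -- training -------------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0

    def constrain(self) -> None:
        for l in self.layers:
            if hasattr(l, "constrain"):
                l.constrain()

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Categorical cross-entropy; accumulates parameter gradients."""
        self.zero_grads()
        z = self.logits(x, training=True)
        p = softmax(z)
        n = len(y)
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        g = p.astype(np.float64)
        g[np.arange(n), y] -= 1.0
        g /= n
        g = g.astype(z.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return float(loss)

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params()]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                state += [l.run_mean.copy(), l.run_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, state[:len(ps)]):
            p[...] = s
        i = len(ps)
        for l in self.layers:
            if isinstance(l, BatchNorm):
                l.run_mean[...] = state[i]
                l.run_var[...] = state[i + 1]
                i += 2

    # -- DeepLIFT -------------------------------------------------------
    def deeplift(self, x: np.ndarray, target_class: int,
                 reference: np.ndarray | None = None) -> np.ndarray:
        """Signed DeepLIFT attribution (Rescale rule) w.r.t. the input.

        ``x`` is a single (C, T) input; the reference defaults to zero.
        Attribution is taken for the pre-softmax score of ``target_class``
        and satisfies summation-to-delta:
        ``sum(attr) == logit(x)[target] - logit(ref)[target]``.
        """
        if not 0 <= target_class < self.spec.n_classes:
            raise ValueError(
                f"target_class {target_class} out of range "
                f"[0, {self.spec.n_classes})"
            )
        if x.shape != (self.spec.n_channels, self.spec.n_samples):
            raise ValueError("input shape mismatch with NetSpec")
        if reference is None:
            reference = np.zeros_like(x)
        h = x[None, None].astype(np.float64)
        r = reference[None, None].astype(np.float64)
        acts_x, acts_r = [h], [r]
        for layer in self.layers:
            h = layer.forward(h, training=False)
            acts_x.append(h)
            r = layer.forward(r, training=False)
            acts_r.append(r)
        m = np.zeros((1, self.spec.n_classes))
        m[0, target_class] = 1.0
        for i in range(len(self.layers) - 1, -1, -1):
            m = self.layers[i].multipliers(
                m, acts_x[i], acts_r[i], acts_x[i + 1], acts_r[i + 1]
            )
        attr = m[0, 0] * (x.astype(np.float64) - reference.astype(np.float64))
        return attr


def build_net(spec: NetSpec, seed: int = 0) -> EEGDecoder:
    """Construct the decoder; raises on invalid shape contracts."""
    return EEGDecoder(spec, seed=seed)
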