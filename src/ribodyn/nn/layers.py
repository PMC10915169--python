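"""NumPy neural-network layers with explicit backward passes.

Every layer exposes ``forward(x, training=False)`` and ``backward(dout)``;
``backward`` accumulates parameter gradients in-place and returns the
gradient with respect to the layer input.  All arithmetic is float64 so
layer outputs can be checked against brute-force oracles at 1e-6.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A named learnable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: parameter-free, stateless by default."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        """Non-learnable state that must survive checkpointing (e.g. BN stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Embedding(Layer):
    """Token-index lookup table: (N, L) int -> (N, L, E)."""

    def __init__(self, name: str, vocab: int, dim: int, rng: np.random.Generator):
        self.vocab = vocab
        self.table = Param(f"{name}.table", rng.normal(0.0, 0.1, size=(vocab, dim)))

    def params(self):
        return [self.table]

    def forward(self, x, training=False):
        idx = np.asarray(x)
        if idx.min() < 0 or idx.max() >= self.vocab:
            raise ValueError("codon index out of range")
        self._idx = idx
        return self.table.data[idx]

    def backward(self, dout):
        np.add.at(
            self.table.grad,
            self._idx.ravel(),
            dout.reshape(-1, self.table.data.shape[1]),
        )
        return None  # integer input has no gradient


class Conv2DSame(Layer):
    """2D convolution over (length, embed) with SAME padding, stride 1.

    Input (N, L, E, Cin) -> output (N, L, E, Cout).  Implemented as a sum
    of per-offset matmuls, matching x_i^f = sum_m x_{i+m} K_m^f + b^f.
    """

    def __init__(self, name, cin, cout, kernel, rng):
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.W = Param(f"{name}.W", _he_init(rng, (kh, kw, cin, cout), kh * kw * cin))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def _pad(self, x):
        ph, pw = self.kh // 2, self.kw // 2
        return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def forward(self, x, training=False):
        N, L, E, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        xp = self._pad(x)
        self._xp_shape, self._x_shape = xp.shape, x.shape
        self._xp = xp
        y = np.broadcast_to(self.b.data, (N, L, E, self.cout)).copy()
        for a in range(self.kh):
            for b in range(self.kw):
                sl = xp[:, a : a + L, b : b + E, :].reshape(-1, cin)
                y += (sl @ self.W.data[a, b]).reshape(N, L, E, self.cout)
        return y

    def backward(self, dout):
        N, L, E, _ = self._x_shape
        d2 = dout.reshape(-1, self.cout)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        dxp = np.zeros(self._xp_shape)
        for a in range(self.kh):
            for b in range(self.kw):
                sl = self._xp[:, a : a + L, b : b + E, :].reshape(-1, self.cin)
                self.W.grad[a, b] += sl.T @ d2
                dxp[:, a : a + L, b : b + E, :] += (d2 @ self.W.data[a, b].T).reshape(
                    N, L, E, self.cin
                )
        ph, pw = self.kh // 2, self.kw // 2
        return dxp[:, ph : ph + L, pw : pw + E, :]


class Conv1DSame(Layer):
    """1D convolution over length with SAME padding, stride 1.

    Input (N, L, Cin) -> output (N, L, Cout).
    """

    def __init__(self, name, cin, cout, kernel, rng):
        self.k, self.cin, self.cout = kernel, cin, cout
        self.W = Param(f"{name}.W", _he_init(rng, (kernel, cin, cout), kernel * cin))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        N, L, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp, self._x_shape = xp, x.shape
        y = np.broadcast_to(self.b.data, (N, L, self.cout)).copy()
        for a in range(self.k):
            y += (xp[:, a : a + L, :].reshape(-1, cin) @ self.W.data[a]).reshape(
                N, L, self.cout
            )
        return y

    def backward(self, dout):
        N, L, _ = self._x_shape
        d2 = dout.reshape(-1, self.cout)
        self.b.grad += dout.sum(axis=(0, 1))
        dxp = np.zeros(self._xp.shape)
        for a in range(self.k):
            sl = self._xp[:, a : a + L, :].reshape(-1, self.cin)
            self.W.grad[a] += sl.T @ d2
            dxp[:, a : a + L, :] += (d2 @ self.W.data[a].T).reshape(N, L, self.cin)
        p = self.k // 2
        return dxp[:, p : p + L, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization over all axes but the last."""

    def __init__(self, name, channels, momentum=0.9, eps=1e-5):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._name = name

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [
            (f"{self._name}.running_mean", self.running_mean),
            (f"{self._name}.running_var", self.running_var),
        ]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training, x.shape)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dout):
        xhat, inv, axes, training, shape = self._cache
        self.beta.grad += dout.sum(axis=axes)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        dxhat = dout * self.gamma.data
        if not training:
            return dxhat * inv
        n = np.prod([shape[a] for a in axes])
        return (
            inv
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )


class Dense(Layer):
    """Affine map over the trailing axis: (..., Cin) -> (..., Cout)."""

    def __init__(self, name, cin, cout, rng):
        self.W = Param(f"{name}.W", _he_init(rng, (cin, cout), cin))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.W.data.shape[0])
        d2 = dout.reshape(-1, self.W.data.shape[1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.data.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LayerNorm(Layer):
    """Per-position normalization over the trailing (channel) axis."""

    def __init__(self, name, channels, eps=1e-5):
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dout):
        xhat, inv = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.beta.grad += dout.sum(axis=axes)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        dxhat = dout * self.gamma.data
        n = dout.shape[-1]
        return (
            inv
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
            )
        )


class MeanPool(Layer):
    """Mean over one axis (embedding-axis pooling or global length pooling)."""

    def __init__(self, axis: int):
        self.axis = axis

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=self.axis)

    def backward(self, dout):
        n = self._shape[self.axis]
        return np.broadcast_to(
            np.expand_dims(dout, self.axis) / n, self._shape
        ).copy()


class MultiHeadAttention(Layer):
    """Scaled dot-product multi-head self-attention.

    a_ij = softmax_j(q_i . k_j / sqrt(K)); h_i = sum_j a_ij v_j; head
    outputs are concatenated.  Dropout (on the attention weights) is
    active only in training mode.
    """

    def __init__(self, name, channels, heads, key_dim, dropout, rng):
        self.H, self.C, self.K = heads, channels, key_dim
        self.dropout = dropout
        std = 1.0 / np.sqrt(channels)
        shape = (heads, channels, key_dim)
        self.Wq = Param(f"{name}.Wq", rng.normal(0, std, shape))
        self.Wk = Param(f"{name}.Wk", rng.normal(0, std, shape))
        self.Wv = Param(f"{name}.Wv", rng.normal(0, std, shape))
        self._rng = rng

    def params(self):
        return [self.Wq, self.Wk, self.Wv]

    @property
    def out_dim(self) -> int:
        return self.H * self.K

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Deterministic attention matrices (H, N, L, L) for inspection."""
        q = np.einsum("nlc,hck->hnlk", x, self.Wq.data)
        k = np.einsum("nlc,hck->hnlk", x, self.Wk.data)
        s = np.einsum("hnik,hnjk->hnij", q, k) / np.sqrt(self.K)
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x, training=False):
        N, L, C = x.shape
        if C != self.C:
            raise ValueError(f"expected {self.C} channels, got {C}")
        q = np.einsum("nlc,hck->hnlk", x, self.Wq.data)
        k = np.einsum("nlc,hck->hnlk", x, self.Wk.data)
        v = np.einsum("nlc,hck->hnlk", x, self.Wv.data)
        s = np.einsum("hnik,hnjk->hnij", q, k) / np.sqrt(self.K)
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        if training and self.dropout > 0:
            keep = self._rng.random(a.shape) >= self.dropout
            ad = a * keep / (1.0 - self.dropout)
        else:
            keep = None
            ad = a
        h = np.einsum("hnij,hnjk->hnik", ad, v)
        self._cache = (x, q, k, v, a, ad, keep)
        return h.transpose(1, 2, 0, 3).reshape(N, L, self.H * self.K)

    def backward(self, dout):
        x, q, k, v, a, ad, keep = self._cache
        N, L, _ = x.shape
        dh = dout.reshape(N, L, self.H, self.K).transpose(2, 0, 1, 3)
        dad = np.einsum("hnik,hnjk->hnij", dh, v)
        dv = np.einsum("hnij,hnik->hnjk", ad, dh)
        if keep is not None:
            da = dad * keep / (1.0 - self.dropout)
        else:
            da = dad
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.K)
        dq = np.einsum("hnij,hnjk->hnik", ds, k)
        dk = np.einsum("hnij,hnik->hnjk", ds, q)
        self.Wq.grad += np.einsum("nlc,hnlk->hck", x, dq)
        self.Wk.grad += np.einsum("nlc,hnlk->hck", x, dk)
        self.Wv.grad += np.einsum("nlc,hnlk->hck", x, dv)
        dx = (
            np.einsum("hnlk,hck->nlc", dq, self.Wq.data)
            + np.einsum("hnlk,hck->nlc", dk, self.Wk.data)
            + np.einsum("hnlk,hck->nlc", dv, self.Wv.data)
        )
        return dx
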