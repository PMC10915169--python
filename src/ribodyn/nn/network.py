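"""Two-branch architecture: sequence branch and reference-density branch.

Each branch applies a stack of convolution blocks (convolution -> batch
normalization -> pointwise fully connected layer with ReLU), pools the
sequence branch's embedding axis, and runs one multi-head attention
block with a feed-forward stage (dense -> layer norm -> ReLU), yielding
a per-position feature map.  The two maps are merged by element-wise
multiplication and a fully connected readout with a final ReLU produces
the non-negative scalar prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .layers import (
    BatchNorm,
    Conv1DSame,
    Conv2DSame,
    Dense,
    Embedding,
    Layer,
    LayerNorm,
    MeanPool,
    MultiHeadAttention,
    Param,
    ReLU,
)


@dataclass
class ModelConfig:
    embed_dim: int = 8
    conv_blocks: int = 5
    conv_kernel: int = 5  # (k, k) for the 2D sequence branch, k for 1D
    filters: int = 32
    attention_heads: int = 10
    key_dim: int = 8
    dropout: float = 0.1
    branch_out_dim: int = 32
    window: int = 20  # W; input windows span 2W+1 codons

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name != "dropout" and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ConvBlock:
    """convolution -> batch norm -> pointwise dense -> ReLU (length preserved)."""

    def __init__(self, name, kind, cin, cout, kernel, rng):
        if kind == "2D":
            self.conv: Layer = Conv2DSame(f"{name}.conv", cin, cout, (kernel, kernel), rng)
        elif kind == "1D":
            self.conv = Conv1DSame(f"{name}.conv", cin, cout, kernel, rng)
        else:
            raise ValueError(f"unknown conv kind {kind!r}")
        self.bn = BatchNorm(f"{name}.bn", cout)
        self.fc = Dense(f"{name}.fc", cout, cout, rng)
        self.act = ReLU()
        self.stages = [self.conv, self.bn, self.fc, self.act]

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def buffers(self):
        return [b for s in self.stages for b in s.buffers()]

    def forward(self, x, training=False):
        for s in self.stages:
            x = s.forward(x, training=training)
        return x

    def backward(self, dout):
        for s in reversed(self.stages):
            dout = s.backward(dout)
        return dout


class Branch:
    """One input branch producing a ``branch_out_dim`` feature vector."""

    def __init__(self, name: str, kind: str, cfg: ModelConfig, rng):
        if kind not in ("sequence", "reference"):
            raise ValueError(f"unknown branch kind {kind!r}")
        self.kind = kind
        self.cfg = cfg
        self.layers: list = []
        if kind == "sequence":
            self.embedding = Embedding(f"{name}.embed", 64, cfg.embed_dim, rng)
            conv_kind, cin = "2D", 1
        else:
            self.embedding = None
            conv_kind, cin = "1D", 1
        for i in range(cfg.conv_blocks):
            self.layers.append(
                ConvBlock(f"{name}.block{i}", conv_kind, cin, cfg.filters,
                          cfg.conv_kernel, rng)
            )
            cin = cfg.filters
        if kind == "sequence":
            self.layers.append(MeanPool(axis=2))  # pool the embedding axis
        self.attn = MultiHeadAttention(
            f"{name}.attn", cfg.filters, cfg.attention_heads, cfg.key_dim,
            cfg.dropout, rng,
        )
        self.layers.append(self.attn)
        self.layers.append(Dense(f"{name}.ff", self.attn.out_dim, cfg.branch_out_dim, rng))
        self.layers.append(LayerNorm(f"{name}.ln", cfg.branch_out_dim))
        self.layers.append(ReLU())
        # output stays per-position (L x branch_out_dim): the merge head needs
        # positional structure to read out the center codon (a global average
        # would make the readout translation-invariant and the center target
        # unrecoverable)

    def params(self):
        ps = list(self.embedding.params()) if self.embedding else []
        for l in self.layers:
            ps.extend(l.params())
        return ps

    def buffers(self):
        bs = []
        for l in self.layers:
            if hasattr(l, "buffers"):
                bs.extend(l.buffers())
        return bs

    def forward(self, x, training=False):
        if self.kind == "sequence":
            x = self.embedding.forward(x, training=training)
            x = x[..., None]  # (N, L, E) -> (N, L, E, 1): one conv channel
        else:
            x = np.asarray(x, dtype=np.float64)[..., None]  # (N, L, 1)
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        if self.kind == "sequence":
            self.embedding.backward(dout[..., 0])
            return None
        return dout[..., 0]


class DensityModel:
    """Sequence + reference-density branches merged by element-wise product.

    Each branch yields a per-position feature map (L x D); the maps are
    multiplied element-wise and a fully connected readout produces
    output = ReLU(w . (z_seq * z_ref) + b).  ``mask_ref=True`` substitutes
    a learned constant vector for the reference-branch features, yielding
    a pure sequence model.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.seq_branch = Branch("seq", "sequence", cfg, rng)
        self.ref_branch = Branch("ref", "reference", cfg, rng)
        L = 2 * cfg.window + 1
        d = L * cfg.branch_out_dim
        self.head_w = Param("head.w", rng.normal(0, 1.0 / np.sqrt(d), size=d))
        # positive bias start: targets are non-negative densities with mean
        # ~1, and a zero start risks a dead final ReLU (zero gradient).
        self.head_b = Param("head.b", np.ones(1))
        self.ref_mask = Param("head.ref_mask", np.ones(cfg.branch_out_dim))
        self._seed = seed

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        return (
            self.seq_branch.params()
            + self.ref_branch.params()
            + [self.head_w, self.head_b, self.ref_mask]
        )

    def buffers(self):
        return self.seq_branch.buffers() + self.ref_branch.buffers()

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {p.name: p.data.copy() for p in self.params()}
        for name, buf in self.buffers():
            d[name] = buf.copy()
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = state[p.name]
        for name, buf in self.buffers():
            buf[...] = state[name]

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        seq: np.ndarray,
        ref: np.ndarray,
        training: bool = False,
        mask_ref: bool = False,
    ) -> np.ndarray:
        seq = np.asarray(seq)
        ref = np.asarray(ref, dtype=np.float64)
        L = 2 * self.cfg.window + 1
        if seq.ndim != 2 or seq.shape[1] != L:
            raise ValueError(f"seq window must be (n, {L}), got {seq.shape}")
        if ref.shape != seq.shape:
            raise ValueError(f"ref window shape {ref.shape} != seq {seq.shape}")
        zc = self.seq_branch.forward(seq, training=training)  # (N, L, D)
        if mask_ref:
            zr = np.broadcast_to(self.ref_mask.data, zc.shape)
        else:
            zr = self.ref_branch.forward(ref, training=training)
        merged = (zc * zr).reshape(zc.shape[0], -1)
        pre = merged @ self.head_w.data + self.head_b.data[0]
        out = np.maximum(pre, 0.0)
        self._cache = (zc, zr, merged, pre, mask_ref)
        return out

    def backward(self, dout: np.ndarray) -> None:
        zc, zr, merged, pre, mask_ref = self._cache
        dpre = dout * (pre > 0)
        self.head_w.grad += merged.T @ dpre
        self.head_b.grad += np.array([dpre.sum()])
        dmerged = (dpre[:, None] * self.head_w.data).reshape(zc.shape)
        dzc = dmerged * zr
        dzr = dmerged * zc
        self.seq_branch.backward(dzc)
        if mask_ref:
            self.ref_mask.grad += dzr.sum(axis=(0, 1))
        else:
            self.ref_branch.backward(dzr)
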