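"""Channel-Spatial Memory-guided Transformer (CSMT) decoder.

Autoregressive caption decoding over the encoder's two attended branches:
the spatial branch supplies the cross-attention **keys**, the channel
branch the **values**.  Each decoder layer is

1. masked multi-head self-attention over the word embeddings, with
   residual + layer norm, producing the queries ``Q_final``;
2. memory-augmented cross-attention: learnable key/value slots are
   projected and concatenated to the visual keys/values along the token
   axis, so the decoder can attend to persistent, data-independent priors
   alongside the image;
3. a position-wise feed-forward network, each sublayer wrapped in the
   post-norm residual pattern with dropout.

Two layers are stacked (the output of one feeds the next); a final affine
head maps to vocabulary logits.  Greedy decoding starts from ``<start>``
and appends argmax tokens until ``<end>`` or the length cap.

Memory-slot concatenation is along the token axis: concatenating along the
feature axis (as a feature-axis ``dim=-1`` concatenation would) cannot grow the
set of attendable positions and is dimensionally inconsistent with the
slot-count ablation, so the token-axis convention of meshed-memory
transformers is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import LayerNorm, Linear, Module, Parameter, Tensor
from .csa_encoder import EncoderOutput
from .dataset_io import END, START

__all__ = [
    "DecoderConfig",
    "MemorySlots",
    "MultiHeadAttention",
    "DecoderLayer",
    "CSMTDecoder",
    "sinusoidal_positions",
    "causal_mask",
    "greedy_decode",
]


@dataclass(frozen=True)
class DecoderConfig:
    vocab_size: int
    feature_dim: int  # channel depth C of the encoder branches
    d_model: int = 1024
    heads: int = 8
    layers: int = 2
    n_mem: int = 40
    d_ff: int | None = None
    dropout: float = 0.1
    max_len: int = 30

    def __post_init__(self):
        if self.d_model % self.heads:
            raise ValueError(f"d_model={self.d_model} not divisible by heads={self.heads}")
        if self.n_mem < 0:
            raise ValueError("n_mem must be >= 0")

    @property
    def ff_dim(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.d_model


def sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding, length x d_model."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    enc = np.zeros((length, d_model))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : d_model - d_model // 2])
    return enc


def causal_mask(length: int) -> np.ndarray:
    """Additive mask forbidding attention to strictly future positions."""
    return np.triu(np.full((length, length), -1e9), k=1)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``heads`` parallel projections."""

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.d_model, self.heads = d_model, heads
        self.d_head = d_model // heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        return x.reshape(b, l, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, lq, _ = q.shape
        qh, kh, vh = self._split(self.w_q(q)), self._split(self.w_k(k)), self._split(self.w_v(v))
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (self.d_head**-0.5)
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = (attn @ vh).transpose(0, 2, 1, 3).reshape(b, lq, self.d_model)
        return self.w_o(out)


class MemorySlots(Module):
    """Learnable key/value slots concatenated to the visual tokens.

    ``augment`` appends ``n_mem`` projected slot rows after the ``N_k``
    visual rows of both keys and values; with ``n_mem == 0`` it is the
    identity.
    """

    def __init__(self, n_mem: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.n_mem, self.d_model = n_mem, d_model
        std = 1.0 / np.sqrt(d_model)
        if n_mem > 0:
            self.k_init = Parameter(rng.normal(0.0, std, size=(n_mem, d_model)))
            self.v_init = Parameter(rng.normal(0.0, std, size=(n_mem, d_model)))
            self.w_k = Parameter(np.eye(d_model) + rng.normal(0.0, std / 10, size=(d_model, d_model)))
            self.w_v = Parameter(np.eye(d_model) + rng.normal(0.0, std / 10, size=(d_model, d_model)))

    def augment(self, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
        if k.shape[1] != v.shape[1]:
            raise ValueError(f"key/value token counts differ: {k.shape[1]} vs {v.shape[1]}")
        if self.n_mem == 0:
            return k, v
        if k.shape[-1] != self.d_model:
            raise ValueError(f"features have dim {k.shape[-1]}, memory expects {self.d_model}")
        b = k.shape[0]
        ones = Tensor(np.ones((b, 1, 1)))
        mem_k = ones * (self.k_init @ self.w_k)
        mem_v = ones * (self.v_init @ self.w_v)
        return ad.concatenate([k, mem_k], axis=1), ad.concatenate([v, mem_v], axis=1)


class DecoderLayer(Module):
    """Word self-attention -> memory-augmented cross-attention -> FFN."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.self_attn = MultiHeadAttention(cfg.d_model, cfg.heads, rng)
        self.cross_attn = MultiHeadAttention(cfg.d_model, cfg.heads, rng)
        self.memory = MemorySlots(cfg.n_mem, cfg.d_model, rng)
        self.ff1 = Linear(cfg.d_model, cfg.ff_dim, rng)
        self.ff2 = Linear(cfg.ff_dim, cfg.d_model, rng)
        self.norm_self = LayerNorm(cfg.d_model)
        self.norm_cross = LayerNorm(cfg.d_model)
        self.norm_ff = LayerNorm(cfg.d_model)
        self._rng = rng

    def _drop(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.cfg.dropout, self._rng, self.training)

    def self_attend_words(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Q_final = AddNorm(MultiHead(S, S, S)) with the causal mask."""
        if x.shape[1] == 0:
            raise ValueError("cannot self-attend an empty sequence")
        return self.norm_self(x + self._drop(self.self_attn(x, x, x, mask)))

    def forward(self, x: Tensor, k: Tensor, v: Tensor, mask: np.ndarray) -> Tensor:
        q_final = self.self_attend_words(x, mask)
        k_final, v_final = self.memory.augment(k, v)
        h = self.norm_cross(q_final + self._drop(self.cross_attn(q_final, k_final, v_final)))
        return self.norm_ff(h + self._drop(self.ff2(self.ff1(h).relu())))


class CSMTDecoder(Module):
    """Stacked CSMT layers over the encoder's (spatial -> K, channel -> V) branches."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        std = 1.0 / np.sqrt(cfg.d_model)
        self.embedding = Parameter(rng.normal(0.0, std, size=(cfg.vocab_size, cfg.d_model)))
        self.proj_k = Linear(cfg.feature_dim, cfg.d_model, rng)
        self.proj_v = Linear(cfg.feature_dim, cfg.d_model, rng)
        self.decoder_layers = [DecoderLayer(cfg, rng) for _ in range(cfg.layers)]
        for i, layer in enumerate(self.decoder_layers):
            setattr(self, f"layer{i}", layer)
        self.head = Linear(cfg.d_model, cfg.vocab_size, rng)
        self._pos = sinusoidal_positions(max(cfg.max_len, 2) + 1, cfg.d_model)
        self._rng = rng

    def embed(self, token_ids: np.ndarray) -> Tensor:
        """Word embeddings + fixed sinusoidal positions."""
        ids = np.asarray(token_ids, dtype=np.int64)
        if ids.max(initial=0) >= self.cfg.vocab_size:
            raise ValueError("token id outside the embedding table")
        x = ad.embedding(self.embedding, ids) * np.sqrt(self.cfg.d_model)
        return x + Tensor(self._pos[: ids.shape[1]])

    def project_branches(self, enc: EncoderOutput) -> tuple[Tensor, Tensor]:
        """Spatial branch -> key path, channel branch -> value path."""
        return self.proj_k(enc.spatial_branch), self.proj_v(enc.channel_branch)

    def forward(self, enc: EncoderOutput, token_ids: np.ndarray) -> Tensor:
        """Teacher-forced logits, batch x S x vocab."""
        ids = np.asarray(token_ids, dtype=np.int64)
        if ids.ndim != 2 or ids.shape[1] == 0:
            raise ValueError(f"token ids must be batch x S with S >= 1, got {ids.shape}")
        k, v = self.project_branches(enc)
        x = ad.dropout(self.embed(ids), self.cfg.dropout, self._rng, self.training)
        mask = causal_mask(ids.shape[1])
        for layer in self.decoder_layers:
            x = layer(x, k, v, mask)
        return self.head(x)


def greedy_decode(model, enc: EncoderOutput, max_len: int = 30) -> list[list[int]]:
    """Deterministic argmax decoding; sequences include <start> and <end>.

    ``model`` needs only a ``forward(enc, ids) -> logits`` method, so stub
    models can be decoded too.
    """
    batch = enc.channel_branch.shape[0]
    ids = np.full((batch, 1), START, dtype=np.int64)
    finished = np.zeros(batch, dtype=bool)
    while ids.shape[1] < max_len and not finished.all():
        logits = model.forward(enc, ids)
        nxt = logits.data[:, -1].argmax(axis=-1)
        nxt = np.where(finished, END, nxt)
        ids = np.concatenate([ids, nxt[:, None]], axis=1)
        finished |= nxt == END
    out = []
    for row in ids:
        seq = row.tolist()
        if END in seq:
            seq = seq[: seq.index(END) + 1]
        out.append(seq)
    return out
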