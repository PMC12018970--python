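"""PS-Loss: margin-based image-text alignment plus token cross-entropy.

The objective has two parts, combined with learnable weights:

* **Image mapping loss** — pooled backbone features (2048-d under the full
  configuration) are mapped by a linear layer to the alignment width
  (default 1198), cosine similarity against every caption's pooled text
  feature forms an N x N matrix S whose diagonal pairs each image with its
  own caption, and the loss per row is ``(1 - S[i,i]) + sum_{j != i}
  max(0, S[i,j] - m)`` with margin ``m = 0.2``.  The hinge runs over
  off-diagonal entries only: a perfect match has S[i,i] = 1 and penalising
  it through the hinge would contradict the loss's purpose.
* **Text cross-entropy** — mean negative log-likelihood of the reference
  tokens under the decoder's softmax, padded positions masked out.

The combination weights are a 2-way softmax over logits, so they stay
strictly positive and sum to 1 (unconstrained weights would collapse to
zero); both start at 0.5 and are optimised by backpropagation.  A fixed
ratio mode reproduces the 0.3:0.7 / 0.5:0.5 / 0.7:0.3 ablation settings.

Text features are mean-pooled ground-truth token embeddings projected to
the alignment width — the simplest choice consistent with aligning against
"all the text features" of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import logging

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Parameter, Tensor

__all__ = [
    "PSLossConfig",
    "ImageTextAligner",
    "LossWeights",
    "similarity_matrix",
    "image_mapping_loss",
    "text_cross_entropy",
    "pool_text_features",
    "combined_loss",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class PSLossConfig:
    margin: float = 0.2
    map_dim: int = 1198
    image_dim: int = 2048
    weight_mode: str = "learnable"  # or "fixed"
    fixed_ratio: tuple[float, float] = (0.5, 0.5)  # (lambda_image, lambda_text)
    sample_fraction: float = 1.0

    def __post_init__(self):
        if self.weight_mode not in ("learnable", "fixed"):
            raise ValueError("weight_mode must be 'learnable' or 'fixed'")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


class LossWeights(Module):
    """(lambda_image, lambda_text) via a 2-way softmax over logits.

    Softmax parameterisation keeps both weights in (0,1) with unit sum
    throughout training; zero-initialised logits give the 0.5/0.5 start.
    """

    def __init__(self, mode: str = "learnable", fixed_ratio: tuple[float, float] = (0.5, 0.5)):
        super().__init__()
        self.mode = mode
        if mode == "learnable":
            self.logits = Parameter(np.zeros(2))
        else:
            total = fixed_ratio[0] + fixed_ratio[1]
            self._fixed = (fixed_ratio[0] / total, fixed_ratio[1] / total)

    def values(self) -> Tensor:
        if self.mode == "learnable":
            return self.logits.softmax(axis=-1)
        return Tensor(np.array(self._fixed))

    @property
    def lambdas(self) -> tuple[float, float]:
        v = self.values().data
        return float(v[0]), float(v[1])


def map_image_features(features: Tensor, mapper: Linear) -> Tensor:
    """Affine map of pooled image features to the alignment width."""
    if features.shape[-1] != mapper.weight.shape[0]:
        raise ValueError(
            f"image features have dim {features.shape[-1]}, mapper expects {mapper.weight.shape[0]}"
        )
    return mapper(features)


def similarity_matrix(i_mapped: Tensor, t: Tensor) -> Tensor:
    """S[i,j] = cosine(i_mapped[i], t[j]); zero-norm rows are epsilon-guarded."""
    if i_mapped.shape[-1] != t.shape[-1]:
        raise ValueError(f"dim mismatch: images {i_mapped.shape[-1]} vs text {t.shape[-1]}")
    for side, name in ((i_mapped, "image"), (t, "text")):
        norms = np.linalg.norm(side.data, axis=-1)
        if np.any(norms < _EPS):
            logger.warning("zero-norm %s feature row(s) in similarity matrix; epsilon-guarded", name)
    i_n = i_mapped * ((i_mapped * i_mapped).sum(axis=-1, keepdims=True) + _EPS) ** -0.5
    t_n = t * ((t * t).sum(axis=-1, keepdims=True) + _EPS) ** -0.5
    return i_n @ t_n.transpose(1, 0)


def image_mapping_loss(s: Tensor, margin: float = 0.2) -> Tensor:
    """Mean over rows of (1 - diagonal) plus the off-diagonal hinge."""
    n, m_ = s.shape
    if n != m_:
        raise ValueError(f"similarity matrix must be square, got {s.shape}")
    eye = np.eye(n)
    diag_term = (Tensor(np.ones(n)) - (s * Tensor(eye)).sum(axis=1)).sum()
    hinge = (s - margin).relu() * Tensor(1.0 - eye)
    return (diag_term + hinge.sum()) / n


def text_cross_entropy(logits: Tensor, targets: np.ndarray, pad_mask: np.ndarray) -> Tensor:
    """Mean NLL of ``targets`` under softmax(logits) at non-pad positions.

    ``logits``: batch x S x V (pre-softmax); ``pad_mask``: 1 where the
    target position counts, 0 at padding.
    """
    targets = np.asarray(targets, dtype=np.int64)
    mask = np.asarray(pad_mask, dtype=np.float64)
    n_valid = mask.sum()
    if n_valid == 0:
        raise ValueError("pad mask excludes every position")
    logp = logits.log_softmax(axis=-1)
    b, s = targets.shape
    picked = logp[np.arange(b)[:, None], np.arange(s)[None, :], targets]
    return -(picked * Tensor(mask)).sum() / n_valid


def pool_text_features(token_embeddings: Tensor, pad_mask: np.ndarray) -> Tensor:
    """Masked mean of ground-truth token embeddings, batch x d."""
    mask = np.asarray(pad_mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("caption with no non-pad tokens")
    summed = (token_embeddings * Tensor(mask[:, :, None])).sum(axis=1)
    return summed * Tensor(1.0 / counts[:, None])


def combined_loss(loss_image: Tensor, loss_text: Tensor, weights: LossWeights) -> Tensor:
    """L = lambda_image * Loss_image + lambda_text * Loss_text."""
    lam = weights.values()
    return lam[0] * loss_image + lam[1] * loss_text


class ImageTextAligner(Module):
    """Bundles the mapping layer, text projection and loss weights.

    ``alignment_loss`` optionally subsamples a seeded fraction of the
    mapped image rows before building the similarity matrix (the text side
    always contributes all features).
    """

    def __init__(self, cfg: PSLossConfig, text_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.mapper = Linear(cfg.image_dim, cfg.map_dim, rng)
        self.text_proj = Linear(text_dim, cfg.map_dim, rng)
        self.weights = LossWeights(cfg.weight_mode, cfg.fixed_ratio)

    def alignment_loss(
        self,
        pooled_image: Tensor,
        pooled_text: Tensor,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        i_mapped = map_image_features(pooled_image, self.mapper)
        t = self.text_proj(pooled_text)
        if self.cfg.sample_fraction < 1.0:
            n = i_mapped.shape[0]
            keep = max(2, int(round(self.cfg.sample_fraction * n)))
            idx = np.sort((rng or np.random.default_rng(0)).choice(n, size=keep, replace=False))
            i_mapped, t = i_mapped[idx], t[idx]
        s = similarity_matrix(i_mapped, t)
        return image_mapping_loss(s, self.cfg.margin)

    def total_loss(self, loss_image: Tensor, loss_text: Tensor) -> Tensor:
        return combined_loss(loss_image, loss_text, self.weights)
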