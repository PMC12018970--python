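"""Multi-attention feature-differentiation encoder.

Two complementary gating mechanisms refine the backbone's feature map F1:

* **Channel attention** squeezes F1 to a per-channel descriptor (mean over
  spatial positions), passes it through a single learned affine map and a
  sigmoid, and rescales each channel — emphasising channels that carry
  condition-relevant semantics.
* **Spatial attention** squeezes F1 to a per-position descriptor (mean over
  channels), maps the flattened H*W vector through a learned affine map and
  a sigmoid, and rescales each position — emphasising lesion regions.

The encoder emits both gated maps as parallel token sequences of the same
shape as flattened F1; downstream the spatial branch feeds the decoder's
key path and the channel branch its value path, jointly realising the
doubled feature map F2.

The squeeze direction is a deliberate reading: the original formulas index
the reduction over the axis they keep, which contradicts their stated
intent (a per-channel global response and an H x W spatial summary).  The
intent reading is the default; ``printed_eq_reading=True`` switches both
descriptors to that literal reduction for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor

__all__ = [
    "EncoderConfig",
    "EncoderOutput",
    "CSAEncoder",
    "channel_descriptor",
    "spatial_descriptor",
]


@dataclass(frozen=True)
class EncoderConfig:
    channels: int
    grid: int  # feature map is grid x grid
    use_channel: bool = True
    use_spatial: bool = True
    printed_eq_reading: bool = False


@dataclass
class EncoderOutput:
    """Parallel attended branches, each batch x N_tokens x C."""

    channel_branch: Tensor  # beta_c flattened; the decoder's V
    spatial_branch: Tensor  # beta_s flattened; the decoder's K

    @property
    def n_tokens(self) -> int:
        return self.channel_branch.shape[1]

    def concatenated(self) -> np.ndarray:
        """Inspection export: both branches stacked along the token axis (2W x H x C reading)."""
        return np.concatenate([self.channel_branch.data, self.spatial_branch.data], axis=1)


def channel_descriptor(f1: Tensor, printed_eq_reading: bool = False) -> Tensor:
    """Squeeze an NCHW map to a per-channel global response (batch x C).

    Default: mean over spatial positions.  The literal reading instead
    averages over the channel axis and broadcasts the result back to C.
    """
    if f1.ndim != 4:
        raise ValueError(f"expected NCHW, got shape {f1.shape}")
    n, c, h, w = f1.shape
    if h * w == 0:
        raise ValueError("feature map has empty spatial extent")
    if printed_eq_reading:
        mean_over_c = f1.mean(axis=1)  # batch x H x W
        return mean_over_c.mean(axis=(1, 2)).reshape(n, 1) * Tensor(np.ones((1, c)))
    return f1.mean(axis=(2, 3))


def spatial_descriptor(f1: Tensor, printed_eq_reading: bool = False) -> Tensor:
    """Squeeze an NCHW map to a spatial summary grid (batch x H x W).

    Default: mean over channels.  The literal reading averages over spatial
    positions and broadcasts the per-channel mean back across the grid.
    """
    if f1.ndim != 4:
        raise ValueError(f"expected NCHW, got shape {f1.shape}")
    n, c, h, w = f1.shape
    if c == 0:
        raise ValueError("feature map has no channels")
    if printed_eq_reading:
        mean_over_hw = f1.mean(axis=(2, 3)).mean(axis=1)  # batch
        return mean_over_hw.reshape(n, 1, 1) * Tensor(np.ones((1, h, w)))
    return f1.mean(axis=1)


class CSAEncoder(Module):
    """Channel + spatial attention over a square NCHW feature map."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c, p = cfg.channels, cfg.grid * cfg.grid
        scale_c = 1.0 / np.sqrt(c)
        scale_s = 1.0 / np.sqrt(p)
        # single affine map + sigmoid per mechanism (no bottleneck reduction)
        self.w_channel = Parameter(rng.uniform(-scale_c, scale_c, size=(c, c)))
        self.w_spatial = Parameter(rng.uniform(-scale_s, scale_s, size=(p, p)))

    def channel_weights(self, f1: Tensor) -> Tensor:
        """Sigmoid channel gate, batch x C, entries strictly in (0,1)."""
        desc = channel_descriptor(f1, self.cfg.printed_eq_reading)
        return (desc @ self.w_channel).sigmoid()

    def spatial_weights(self, f1: Tensor) -> Tensor:
        """Sigmoid spatial gate, batch x H x W, entries strictly in (0,1)."""
        n, _, h, w = f1.shape
        desc = spatial_descriptor(f1, self.cfg.printed_eq_reading).reshape(n, h * w)
        return (desc @ self.w_spatial).sigmoid().reshape(n, h, w)

    def channel_attention(self, f1: Tensor) -> Tensor:
        """beta_c: each channel of F1 scaled by its learned gate."""
        n, c, _, _ = f1.shape
        return f1 * self.channel_weights(f1).reshape(n, c, 1, 1)

    def spatial_attention(self, f1: Tensor) -> Tensor:
        """beta_s: each position of F1 scaled by its learned gate."""
        n, _, h, w = f1.shape
        return f1 * self.spatial_weights(f1).reshape(n, 1, h, w)

    def forward(self, f1: Tensor) -> EncoderOutput:
        """Gate F1 along both axes and flatten each branch to tokens x C.

        Ablation flags bypass a mechanism entirely (its branch passes F1
        through unchanged), mirroring the channel-only / spatial-only
        configurations.
        """
        n, c, h, w = f1.shape
        if h != self.cfg.grid or w != self.cfg.grid or c != self.cfg.channels:
            raise ValueError(f"feature map {f1.shape} does not match encoder config {self.cfg}")
        beta_c = self.channel_attention(f1) if self.cfg.use_channel else f1
        beta_s = self.spatial_attention(f1) if self.cfg.use_spatial else f1
        flat = lambda t: t.reshape(n, c, h * w).transpose(0, 2, 1)  # noqa: E731
        return EncoderOutput(channel_branch=flat(beta_c), spatial_branch=flat(beta_s))
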