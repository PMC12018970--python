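"""Visual feature extraction: grouped-bottleneck (ResNeXt-style) backbones.

The captioner consumes a spatial grid of channel vectors rather than a
pooled embedding: the backbone drops the usual global-pool/classifier head
and emits ``batch x out_tokens x out_channels`` token sequences, flattened
from the final feature map in row-major order.

Two standard configurations are provided:

* :func:`resnext101_config` — the full ResNeXt101-32x4d layout (cardinality 32,
  4 channels per group, stages of 3/4/23/3 blocks).  The last stage keeps
  stride 1 so the 224x224 input yields a 14x14 grid = 196 tokens of 2048
  channels.
* :func:`tiny_config` — a two-layer desk-scale backbone honouring the same
  contract (16 tokens x 32 channels by default) for tests and demos.

Blocks are normalisation-free (He-scaled init); ImageNet-pretrained weights
can be loaded from a user-supplied checkpoint via ``load_state_dict`` when
``pretrained`` is set, and ``trainable_fraction`` controls how many trailing
stages receive gradient updates during fine-tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor

__all__ = [
    "BackboneConfig",
    "GroupedBottleneck",
    "ResNeXtBackbone",
    "resnext101_config",
    "tiny_config",
    "extract_features",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Layout of a grouped-bottleneck backbone.

    ``cardinality`` parallel grouped-convolution paths of ``group_width``
    channels each give the first stage a mid width of
    ``cardinality * group_width`` (doubling per stage).
    """

    cardinality: int = 32
    group_width: int = 4
    out_tokens: int = 196
    out_channels: int = 2048
    pretrained: bool = False
    trainable_fraction: float = 0.25
    input_size: int = 224
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: int | None = 2  # 2x2 stride-2 max pool when set
    stage_blocks: tuple[int, ...] = (3, 4, 23, 3)
    stage_channels: tuple[int, ...] = (256, 512, 1024, 2048)
    stage_strides: tuple[int, ...] = (1, 2, 2, 1)
    final_pool: int | None = None  # trailing average pool (kernel = stride)

    def __post_init__(self):
        grid = math.isqrt(self.out_tokens)
        if grid * grid != self.out_tokens:
            raise ValueError(f"out_tokens={self.out_tokens} is not a perfect square")
        if len(self.stage_blocks) != len(self.stage_channels) or len(self.stage_blocks) != len(self.stage_strides):
            raise ValueError("stage_blocks, stage_channels and stage_strides must align")
        if self.stage_channels[-1] != self.out_channels:
            raise ValueError("last stage width must equal out_channels")
        if self.grid_size() != grid:
            raise ValueError(
                f"configured strides give a {self.grid_size()}x{self.grid_size()} grid, "
                f"but out_tokens={self.out_tokens} needs {grid}x{grid}"
            )

    def mid_channels(self, stage: int) -> int:
        return self.cardinality * self.group_width * (2**stage)

    def grid_size(self) -> int:
        size = self.input_size // self.stem_stride
        if self.stem_pool:
            size //= 2
        for s in self.stage_strides:
            size //= s
        if self.final_pool:
            size //= self.final_pool
        return size


def resnext101_config(pretrained: bool = False) -> BackboneConfig:
    """ResNeXt101-32x4d layout emitting 196 tokens of 2048 channels."""
    return BackboneConfig(pretrained=pretrained)


def tiny_config(out_tokens: int = 16, out_channels: int = 32) -> BackboneConfig:
    """A two-layer backbone with the same output contract, for desk-scale runs."""
    return BackboneConfig(
        cardinality=4,
        group_width=4,
        out_tokens=out_tokens,
        out_channels=out_channels,
        trainable_fraction=1.0,
        stem_channels=16,
        stem_kernel=8,
        stem_stride=8,
        stem_pool=None,
        stage_blocks=(1,),
        stage_channels=(out_channels,),
        stage_strides=(1,),
        final_pool=224 // (8 * math.isqrt(out_tokens)),
    )


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class GroupedBottleneck(Module):
    """1x1 reduce -> grouped 3x3 -> 1x1 expand -> residual add -> ReLU.

    The grouped convolution runs ``cardinality`` parallel paths; summing the
    per-group outputs back to the expanded width is exactly the 1x1 expand
    convolution applied to the concatenated group outputs.
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, cardinality: int, stride: int, rng: np.random.Generator):
        super().__init__()
        if mid_ch % cardinality:
            raise ValueError(f"mid channels {mid_ch} not divisible by cardinality {cardinality}")
        self.cardinality = cardinality
        self.stride = stride
        self.in_channels, self.mid_channels, self.out_channels = in_ch, mid_ch, out_ch
        self.w_reduce = Parameter(_he(rng, (mid_ch, in_ch, 1, 1)))
        self.w_group = Parameter(_he(rng, (mid_ch, mid_ch // cardinality, 3, 3)))
        self.w_expand = Parameter(_he(rng, (out_ch, mid_ch, 1, 1)))
        if in_ch != out_ch or stride != 1:
            self.w_proj = Parameter(_he(rng, (out_ch, in_ch, 1, 1)))
        else:
            self.w_proj = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        h = ad.conv2d(x, self.w_reduce).relu()
        h = ad.conv2d(h, self.w_group, stride=self.stride, padding=1, groups=self.cardinality).relu()
        h = ad.conv2d(h, self.w_expand)
        shortcut = x if self.w_proj is None else ad.conv2d(x, self.w_proj, stride=self.stride)
        return (h + shortcut).relu()


class ResNeXtBackbone(Module):
    """Stem + grouped-bottleneck stages emitting a flattened token grid."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.w_stem = Parameter(_he(rng, (cfg.stem_channels, 3, cfg.stem_kernel, cfg.stem_kernel)))
        in_ch = cfg.stem_channels
        self.stages: list[list[GroupedBottleneck]] = []
        for si, (n_blocks, out_ch, stride) in enumerate(zip(cfg.stage_blocks, cfg.stage_channels, cfg.stage_strides)):
            stage = []
            for bi in range(n_blocks):
                blk = GroupedBottleneck(
                    in_ch, cfg.mid_channels(si), out_ch, cfg.cardinality, stride if bi == 0 else 1, rng
                )
                setattr(self, f"stage{si}_block{bi}", blk)
                stage.append(blk)
                in_ch = out_ch
            self.stages.append(stage)
        self.set_trainable(cfg.trainable_fraction)

    def set_trainable(self, fraction: float) -> None:
        """Freeze all but the trailing ``fraction`` of stages (stem included in the leading part)."""
        n_stages = len(self.stages)
        n_train = int(math.ceil(fraction * n_stages)) if fraction > 0 else 0
        self.w_stem.requires_grad = fraction >= 1.0
        for si, stage in enumerate(self.stages):
            trainable = si >= n_stages - n_train
            for blk in stage:
                for p in blk.parameters():
                    p.requires_grad = trainable

    def feature_map(self, images: Tensor) -> Tensor:
        """Forward to the final NCHW feature map (no pooling head)."""
        if images.ndim != 4 or images.shape[1:] != (3, self.cfg.input_size, self.cfg.input_size):
            raise ValueError(
                f"expected batch x 3 x {self.cfg.input_size} x {self.cfg.input_size}, got {images.shape}"
            )
        pad = self.cfg.stem_kernel // 2 if self.cfg.stem_kernel % 2 else 0
        h = ad.conv2d(images, self.w_stem, stride=self.cfg.stem_stride, padding=pad).relu()
        if self.cfg.stem_pool:
            h = ad.max_pool2d(h, self.cfg.stem_pool, 2)
        for stage in self.stages:
            for blk in stage:
                h = blk(h)
        if self.cfg.final_pool:
            h = ad.avg_pool2d(h, self.cfg.final_pool)
        return h

    def forward(self, images: Tensor) -> Tensor:
        """Flattened token sequence, batch x out_tokens x out_channels (row-major grid)."""
        fmap = self.feature_map(images)
        n, c, hh, ww = fmap.shape
        if hh * ww != self.cfg.out_tokens or c != self.cfg.out_channels:
            raise ValueError(f"feature map {fmap.shape} violates the {self.cfg.out_tokens}x{self.cfg.out_channels} contract")
        return fmap.reshape(n, c, hh * ww).transpose(0, 2, 1)


def extract_features(images: np.ndarray | Tensor, model: ResNeXtBackbone) -> Tensor:
    """Convenience wrapper: batch of 3x224x224 arrays -> batch x N_tokens x C."""
    if not isinstance(images, Tensor):
        images = Tensor(np.asarray(images))
    return model(images)
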