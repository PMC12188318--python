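"""Multi-scale 2D feature extraction and geometry-informed feature pooling.

A residual CNN turns an x-ray projection into a stack of feature maps at
power-of-two downscales. Each liver surface node is projected onto the
detector with the cone-beam geometry of that projection, and its feature
vector is pooled by bilinear interpolation of the four neighboring feature
pixels on every map, then concatenated across maps. This ties the condition
fed to the downstream networks to the actual imaging geometry, which is what
makes the models angle-agnostic.

The default backbone is a 50-layer bottleneck residual network whose four
stage outputs carry 256 + 512 + 1024 + 2048 = 3840 channels; a tiny
configuration is provided for CPU-scale experiments. The backbone is trained
jointly with whichever downstream model consumes it, so the rigid-alignment
model and the diffusion model each own a separate extractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, bilinear2d, concat, relu, reshape
from .core import SurfacePointCloud
from .nn import Conv2d, Module
from .projector import ConeBeamGeometry, ProjectionImage, project_points

__all__ = [
    "BackboneConfig",
    "FeatureExtractor",
    "FeatureStack",
    "PooledFeatures",
    "extract_feature_stack",
    "pool_features",
    "global_features",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Residual feature-extractor layout.

    ``stage_channels`` are the per-stage output channels (their sum is the
    pooled feature width F); ``stage_strides`` are relative to the stem
    output, so map downscales are ``stem_stride * cumprod(stage_strides)``.
    """

    stage_channels: tuple = (256, 512, 1024, 2048)
    stage_blocks: tuple = (3, 4, 6, 3)
    stage_strides: tuple = (2, 2, 2, 2)
    stem_channels: int = 64
    stem_stride: int = 2
    bottleneck: bool = True

    def __post_init__(self):
        if not (len(self.stage_channels) == len(self.stage_blocks)
                == len(self.stage_strides)):
            raise ValueError("per-stage tuples must have equal length")

    @property
    def total_channels(self) -> int:
        return int(sum(self.stage_channels))

    @property
    def downscales(self) -> tuple:
        out, ds = [], self.stem_stride
        for s in self.stage_strides:
            ds *= s
            out.append(ds)
        return tuple(out)

    @classmethod
    def tiny(cls, stage_channels=(8, 16, 32)) -> "BackboneConfig":
        """CPU-scale variant; keeps the first map at full resolution so
        sub-pixel feature shifts (the depth cue of cone-beam magnification)
        survive pooling."""
        return cls(stage_channels=tuple(stage_channels),
                   stage_blocks=(1,) * len(stage_channels),
                   stage_strides=(1,) + (2,) * (len(stage_channels) - 1),
                   stem_channels=8, stem_stride=1, bottleneck=False)


class _BasicBlock(Module):
    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.proj = (Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0)
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x):
        h = self.conv2(relu(self.conv1(x)))
        skip = self.proj(x) if self.proj is not None else x
        return relu(h + skip)


class _BottleneckBlock(Module):
    def __init__(self, c_in, c_out, stride, rng):
        width = max(c_out // 4, 1)
        self.conv1 = Conv2d(c_in, width, 1, rng, pad=0)
        self.conv2 = Conv2d(width, width, 3, rng, stride=stride)
        self.conv3 = Conv2d(width, c_out, 1, rng, pad=0)
        self.proj = (Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0)
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x):
        h = self.conv3(relu(self.conv2(relu(self.conv1(x)))))
        skip = self.proj(x) if self.proj is not None else x
        return relu(h + skip)


class FeatureExtractor(Module):
    """Residual CNN returning one feature map per stage."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        self.stem = Conv2d(1, config.stem_channels, 3, rng,
                           stride=config.stem_stride)
        Block = _BottleneckBlock if config.bottleneck else _BasicBlock
        self.stages = []
        c_in = config.stem_channels
        for c_out, n_blocks, stride in zip(config.stage_channels,
                                           config.stage_blocks,
                                           config.stage_strides):
            blocks = [Block(c_in, c_out, stride, rng)]
            blocks += [Block(c_out, c_out, 1, rng) for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
            c_in = c_out

    def __call__(self, x: Tensor) -> list[Tensor]:
        h = relu(self.stem(x))
        maps = []
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h)
            maps.append(h)
        return maps


@dataclass
class FeatureStack:
    """Per-stage 2D feature maps with their downscale factors."""

    maps: list                     # list of Tensor, each (C_i, H_i, W_i)
    downscales: tuple

    @property
    def total_channels(self) -> int:
        return int(sum(m.data.shape[0] for m in self.maps))


@dataclass
class PooledFeatures:
    """Per-node pooled feature vectors (N, F); out-of-view rows are zero."""

    features: Tensor
    valid: np.ndarray = field(default=None)

    @property
    def data(self) -> np.ndarray:
        return self.features.data

    @property
    def n_nodes(self) -> int:
        return self.features.data.shape[0]


def extract_feature_stack(proj: ProjectionImage,
                          extractor: FeatureExtractor) -> FeatureStack:
    """Run the backbone on a (standardized) projection."""
    g = np.asarray(proj.pixels, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("projection contains non-finite values")
    g = (g - g.mean()) / (g.std() + 1e-6)
    maps = extractor(Tensor(g[None]))
    return FeatureStack(maps=maps, downscales=extractor.config.downscales)


def pool_features(stack: FeatureStack, geom: ConeBeamGeometry,
                  cloud: SurfacePointCloud) -> PooledFeatures:
    """Pool a per-node feature vector from every map of the stack.

    Each node is projected to continuous detector pixel coordinates, the
    coordinate is divided by the map's downscale factor (pixel-center
    convention shared with the projector), and the map is sampled bilinearly.
    Nodes outside the detector (or behind the source) pool zeros.
    """
    uv, valid = project_points(geom, cloud.coords)
    if valid.mean() < 0.5:
        warnings.warn(
            f"{(~valid).sum()}/{valid.size} nodes project outside the "
            "detector; check the imaging geometry", stacklevel=2)
    uv_safe = np.where(np.isfinite(uv), uv, 0.0)
    mask = valid.astype(np.float64)[:, None]
    parts = [bilinear2d(m, uv_safe / ds) * mask
             for m, ds in zip(stack.maps, stack.downscales)]
    return PooledFeatures(features=concat(parts, axis=1), valid=valid)


def global_features(stack: FeatureStack, n_nodes: int) -> PooledFeatures:
    """Spatially averaged backbone features, tiled per node.

    This is the geometry-agnostic conditioning used by the no-geometry-pooling
    ablation variant: every node receives the same global feature vector.
    """
    parts = []
    for m in stack.maps:
        c, h, w = m.data.shape
        flat = reshape(m, (c, h * w))
        parts.append(flat @ np.full((h * w, 1), 1.0 / (h * w)))  # (c, 1)
    g = reshape(concat(parts, axis=0), (1, -1))  # (1, F)
    tiled = Tensor(np.ones((n_nodes, 1))) @ g
    return PooledFeatures(features=tiled, valid=np.ones(n_nodes, dtype=bool))
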