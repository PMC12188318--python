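"""Point-voxel network: the per-node regression backbone.

Two branches process each point cloud: a voxel branch that normalizes the
point coordinates to their gravity center, scales them into the unit sphere,
averages point features into a regular grid, applies 3D convolutions, and
maps the result back to the points by trilinear devoxelization; and a point
branch that applies a shared per-point MLP, preserving fine-grained detail.
Branch outputs are fused by addition. An optional sinusoidal timestep
embedding (for the diffusion denoiser) is projected and added to the hidden
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, relu, trilinear3d, voxelize_mean
from .nn import Linear, Module, timestep_embedding

__all__ = ["PVCNNConfig", "PointVoxelNet", "normalize_to_unit_sphere",
           "voxel_coords"]


@dataclass(frozen=True)
class PVCNNConfig:
    feature_width: int          # condition width F per node
    hidden: int = 32
    grid_res: int = 9           # odd: a lone point lands on a voxel center
    n_blocks: int = 2
    with_time: bool = False
    # If True, the MLP input coordinates are unit-sphere normalized (suits
    # fixed anatomical clouds in mm); if False they enter raw (suits the
    # diffusion state, which is already O(1) and whose centroid carries the
    # signal being denoised). Voxelization always uses normalized coords.
    center_input: bool = True


def normalize_to_unit_sphere(coords: np.ndarray) -> np.ndarray:
    """Translate to the centroid and scale the cloud into the unit sphere."""
    c = coords - coords.mean(axis=0)
    r = np.linalg.norm(c, axis=1).max()
    return c / (r if r > 1e-12 else 1.0)


def voxel_coords(coords: np.ndarray, grid_res: int) -> tuple[np.ndarray, np.ndarray]:
    """Continuous grid coordinates in [0, R-1]^3 and flattened nearest-voxel
    indices for a point cloud (after unit-sphere normalization)."""
    pn = normalize_to_unit_sphere(coords)
    gc = (pn + 1.0) * 0.5 * (grid_res - 1)
    nearest = np.clip(np.rint(gc).astype(np.intp), 0, grid_res - 1)
    flat = (nearest[:, 0] * grid_res + nearest[:, 1]) * grid_res + nearest[:, 2]
    return gc, flat


class _PVBlock(Module):
    def __init__(self, hidden: int, rng: np.random.Generator):
        from .nn import Conv3d

        self.point = Linear(hidden, hidden, rng)
        self.conv = Conv3d(hidden, hidden, 3, rng)

    def __call__(self, h: Tensor, gc: np.ndarray, flat_idx: np.ndarray,
                 grid_res: int) -> Tensor:
        hp = relu(self.point(h))
        grid = voxelize_mean(h, flat_idx, (grid_res,) * 3)
        hv = trilinear3d(relu(self.conv(grid)), gc)
        return relu(hp + hv)


class PointVoxelNet(Module):
    """(N, 3 + F) per-node input -> (N, 3) per-node output."""

    def __init__(self, config: PVCNNConfig, rng: np.random.Generator):
        self.config = config
        h = config.hidden
        self.inp = Linear(3 + config.feature_width, h, rng)
        self.time_proj = Linear(h, h, rng) if config.with_time else None
        self.blocks = [_PVBlock(h, rng) for _ in range(config.n_blocks)]
        self.out = Linear(h, 3, rng)

    def __call__(self, coords: np.ndarray, features, t: int | None = None) -> Tensor:
        """coords: (N, 3) constant point positions (the cloud being
        processed); features: (N, F) Tensor or array; t: diffusion step."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[0] == 0:
            raise ValueError("empty point cloud")
        feats = features if isinstance(features, Tensor) else Tensor(features)
        if feats.data.shape != (coords.shape[0], self.config.feature_width):
            raise ValueError(
                f"expected features ({coords.shape[0]}, "
                f"{self.config.feature_width}), got {feats.data.shape}")
        mlp_coords = (normalize_to_unit_sphere(coords)
                      if self.config.center_input else coords)
        x = concat([Tensor(mlp_coords), feats], axis=1)
        h = self.inp(x)
        if self.time_proj is not None:
            if t is None:
                raise ValueError("this network requires a timestep")
            emb = timestep_embedding(int(t), self.config.hidden)
            h = h + self.time_proj(Tensor(emb[None]))
        h = relu(h)
        gc, flat_idx = voxel_coords(coords, self.config.grid_res)
        for blk in self.blocks:
            h = blk(h, gc, flat_idx, self.config.grid_res)
        return self.out(h)
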