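"""Core geometric containers shared across the package.

Axis convention throughout: ``x`` = left-right (LR), ``y`` = anterior-posterior
(AP), ``z`` = superior-inferior (SI); all coordinates and displacements are in
millimetres, in the patient frame with the treatment isocenter at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfacePointCloud", "DisplacementField", "save_ply", "load_ply"]


@dataclass
class SurfacePointCloud:
    """Liver-boundary node coordinates (mm), shape (N, 3)."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if self.coords.shape[0] < 4:
            raise ValueError("a surface point cloud needs at least 4 nodes")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def translated(self, shift) -> "SurfacePointCloud":
        return SurfacePointCloud(self.coords + np.asarray(shift, dtype=np.float64))


@dataclass
class DisplacementField:
    """Per-node displacement 3-vectors (mm), node-aligned to a reference cloud."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (N, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacements must be finite")

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    def __neg__(self) -> "DisplacementField":
        return DisplacementField(-self.vectors)


def save_ply(points: np.ndarray, path) -> None:
    """Write an (N, 3) point set (mm) to a binary little-endian PLY file."""
    import trimesh

    trimesh.points.PointCloud(np.asarray(points, dtype=np.float64)).export(str(path))


def load_ply(path) -> np.ndarray:
    """Read an (N, 3) point set from a PLY file."""
    import trimesh

    obj = trimesh.load(str(path))
    return np.asarray(obj.vertices, dtype=np.float64)
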