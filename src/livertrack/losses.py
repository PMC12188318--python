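"""Composite training objective and the k-nearest-neighbor graph it needs.

Every loss accepts either plain numpy arrays or autodiff ``Tensor`` objects,
so the same formulas serve evaluation code and gradient-based training.

The total objective is

    L_total = L_noise + lambda_sim * L_sim + lambda_lap * L_lap
              + lambda_eng * L_eng

with L_noise the mean squared error between true and predicted diffusion
noise, L_sim an anisotropically weighted point-cloud MSE (the SI axis is
up-weighted because respiratory liver motion is SI-dominant), L_lap a
Laplacian-coordinate regularizer discouraging unrealistic local deformation,
and L_eng the mean deformation energy of the displacement field. L_eng can be
negative on asymmetric kNN graphs (the graph Laplacian is not symmetric);
this is a property of the definition and is left as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, tsum
from .core import SurfacePointCloud

__all__ = [
    "NeighborGraph",
    "LossWeights",
    "knn_graph",
    "denoising_loss",
    "weighted_mse",
    "laplacian_coords",
    "laplacian_loss",
    "energy_loss",
    "total_loss",
]


@dataclass
class LossWeights:
    lambda_sim: float = 1.0
    lambda_lap: float = 0.01
    lambda_eng: float = 0.01
    si_weight: float = 3.0

    def __post_init__(self):
        for name in ("lambda_sim", "lambda_lap", "lambda_eng", "si_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NeighborGraph:
    """k nearest neighbors per node (no self-loops), plus the graph Laplacian
    matrix L = I - A/k used by the Laplacian-coordinate losses."""

    indices: np.ndarray  # (N, k) int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        n, k = self.indices.shape
        if k >= n:
            raise ValueError("k must be smaller than the node count")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("self-loops are not allowed")
        self._lap = None

    @property
    def n_nodes(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]

    def laplacian_matrix(self) -> np.ndarray:
        if self._lap is None:
            n, k = self.indices.shape
            lap = np.eye(n)
            rows = np.repeat(np.arange(n), k)
            np.add.at(lap, (rows, self.indices.reshape(-1)), -1.0 / k)
            self._lap = lap
        return self._lap


def knn_graph(cloud, k: int = 8) -> NeighborGraph:
    """Euclidean k nearest neighbors, self excluded.

    Distance ties are broken by ascending node index, which makes the graph
    deterministic even for duplicated coordinates.
    """
    coords = cloud.coords if isinstance(cloud, SurfacePointCloud) else np.asarray(cloud)
    n = coords.shape[0]
    if n <= k:
        raise ValueError("need more nodes than neighbors")
    indices = np.empty((n, k), dtype=np.intp)
    idx = np.arange(n)
    chunk = max(1, int(2e7) // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = np.sum((coords[lo:hi, None, :] - coords[None, :, :]) ** 2, axis=2)
        d2[np.arange(hi - lo), idx[lo:hi]] = np.inf  # exclude self
        for r in range(hi - lo):
            order = np.lexsort((idx, d2[r]))
            indices[lo + r] = order[:k]
    return NeighborGraph(indices)


def _coords(x):
    if isinstance(x, SurfacePointCloud):
        return x.coords
    return x


def _sum(x):
    return tsum(x) if isinstance(x, Tensor) else float(np.sum(x))


def _check_aligned(a, b):
    sa = a.data.shape if isinstance(a, Tensor) else np.shape(a)
    sb = b.data.shape if isinstance(b, Tensor) else np.shape(b)
    if sa != sb:
        raise ValueError(f"shape mismatch: {sa} vs {sb}")


def denoising_loss(eps_true, eps_pred):
    """Mean over nodes and coordinates of the squared noise residual."""
    _check_aligned(eps_true, eps_pred)
    d = eps_pred - eps_true
    size = d.data.size if isinstance(d, Tensor) else d.size
    return _sum(d * d) / size


def weighted_mse(pred_cloud, tar_cloud, si_weight: float = 3.0):
    """Per-node squared distance with the SI (z) term scaled, averaged over
    nodes: mean_p (dx^2 + dy^2 + si_weight * dz^2)."""
    p, t = _coords(pred_cloud), _coords(tar_cloud)
    _check_aligned(p, t)
    d = p - t
    w = np.array([1.0, 1.0, float(si_weight)])
    n = d.data.shape[0] if isinstance(d, Tensor) else d.shape[0]
    return _sum(d * d * w) / n


def laplacian_coords(cloud, graph: NeighborGraph):
    """delta_p = p - mean of p's neighbors, per node (N, 3)."""
    c = _coords(cloud)
    return graph.laplacian_matrix() @ c


def laplacian_loss(cloud_before, cloud_after, graph: NeighborGraph):
    """(1/N) sum_p ||delta'_p - delta_p||^2 on a shared neighbor graph."""
    b, a = _coords(cloud_before), _coords(cloud_after)
    _check_aligned(b, a)
    d = graph.laplacian_matrix() @ (a - b)
    n = d.data.shape[0] if isinstance(d, Tensor) else d.shape[0]
    return _sum(d * d) / n


def energy_loss(dvf, graph: NeighborGraph):
    """Mean deformation energy: (1/N) sum_p dvf_p . (L dvf)_p.

    Zero for any spatially uniform field; may be negative because the kNN
    graph Laplacian is asymmetric.
    """
    v = dvf.vectors if hasattr(dvf, "vectors") else dvf
    vshape = v.data.shape if isinstance(v, Tensor) else np.shape(v)
    if vshape[0] != graph.n_nodes:
        raise ValueError("DVF and graph node counts differ")
    lap = graph.laplacian_matrix() @ v
    return _sum(v * lap) / vshape[0]


def total_loss(noise, sim, lap, eng, weights: LossWeights | None = None):
    """L_total = L_noise + l_sim L_sim + l_lap L_lap + l_eng L_eng."""
    w = weights or LossWeights()
    for name, part in (("noise", noise), ("sim", sim), ("lap", lap), ("eng", eng)):
        val = part.data if isinstance(part, Tensor) else part
        if not np.all(np.isfinite(val)):
            raise ValueError(f"loss component '{name}' is not finite")
    return (noise + w.lambda_sim * sim + w.lambda_lap * lap
            + w.lambda_eng * eng)
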