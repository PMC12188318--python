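"""Rigid alignment model: the liver's overall translation from one projection.

A point-voxel network consumes the prior reference surface nodes together
with their geometry-pooled projection features and emits a per-node
3-vector field; the rigid shift is the arithmetic mean over nodes. The
feature-extraction backbone is trained jointly with the network using an MSE
loss against the known shifts. Diffusion-based deformable estimation uses
this shift to re-center its output (diffusion models produce near-zero-mean
fields), so the rigid model carries the bulk translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, tsum
from .core import SurfacePointCloud
from .nn import Adam, Module
from .pooling import (BackboneConfig, FeatureExtractor, PooledFeatures,
                      extract_feature_stack, global_features, pool_features)
from .projector import ConeBeamGeometry, ProjectionImage
from .pvcnn import PVCNNConfig, PointVoxelNet

__all__ = ["RigidModel", "RigidSample", "predict_rigid_shift", "train_rigid"]


@dataclass
class RigidSample:
    cloud_ref: SurfacePointCloud
    projection: ProjectionImage
    geometry: ConeBeamGeometry
    shift_true: np.ndarray  # (3,) mm


class RigidModel(Module):
    """Feature extractor + point-voxel regressor; ``pool_mode`` selects
    geometry-informed pooling ('geometry') or the global-feature ablation
    ('global')."""

    def __init__(self, backbone: BackboneConfig, hidden: int = 32,
                 grid_res: int = 9, n_blocks: int = 2,
                 pool_mode: str = "geometry", seed: int = 0):
        if pool_mode not in ("geometry", "global"):
            raise ValueError("pool_mode must be 'geometry' or 'global'")
        rng = np.random.default_rng(seed)
        self.extractor = FeatureExtractor(backbone, rng)
        self.net = PointVoxelNet(
            PVCNNConfig(feature_width=backbone.total_channels, hidden=hidden,
                        grid_res=grid_res, n_blocks=n_blocks, with_time=False),
            rng)
        self.pool_mode = pool_mode
        self.trained = False

    def pooled(self, proj: ProjectionImage, geom: ConeBeamGeometry,
               cloud: SurfacePointCloud) -> PooledFeatures:
        stack = extract_feature_stack(proj, self.extractor)
        if self.pool_mode == "global":
            return global_features(stack, cloud.n_nodes)
        return pool_features(stack, geom, cloud)

    def shift_tensor(self, proj, geom, cloud) -> Tensor:
        feats = self.pooled(proj, geom, cloud)
        return predict_rigid_shift(self, cloud, feats, as_tensor=True)

    def predict(self, proj: ProjectionImage, geom: ConeBeamGeometry,
                cloud: SurfacePointCloud) -> np.ndarray:
        """Estimated rigid shift (3,) in mm."""
        return self.shift_tensor(proj, geom, cloud).data[0]


def predict_rigid_shift(model: RigidModel, cloud_ref: SurfacePointCloud,
                        features: PooledFeatures, as_tensor: bool = False):
    """Per-node 3-vectors from [coords || features], averaged into one shift."""
    if features.n_nodes != cloud_ref.n_nodes:
        raise ValueError("features are not row-aligned with the cloud")
    per_node = model.net(cloud_ref.coords, features.features)  # (N, 3)
    n = cloud_ref.n_nodes
    shift = np.full((1, n), 1.0 / n) @ per_node  # (1, 3) mean over nodes
    return shift if as_tensor else shift.data[0]


def train_rigid(dataset: list[RigidSample], epochs: int = 10,
                lr: float = 1e-3, seed: int = 0,
                model: RigidModel | None = None,
                backbone: BackboneConfig | None = None,
                batch_size: int = 4, lr_min: float | None = None,
                **model_kwargs) -> tuple[RigidModel, list]:
    """Fit the per-node displacement output to the known rigid shifts (MSE).

    The ground-truth rigid motion is a spatially uniform field, so the MSE
    is taken over every node's output vector; the inference-time average
    then acts purely as a variance reducer. The pooling backbone is updated
    jointly. With ``lr_min`` set, the
    learning rate follows a per-epoch cosine decay from ``lr`` to ``lr_min``;
    the low-rate tail matters in practice — the weak depth (along-ray) cue is
    fitted late, after the strong in-plane cues have converged. Returns the
    trained model and the per-epoch mean loss trajectory (mm^2).
    Deterministic per seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if model is None:
        model = RigidModel(backbone or BackboneConfig.tiny(), seed=seed,
                           **model_kwargs)
    params = model.parameters()
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = []
    for epoch in range(epochs):
        if lr_min is not None and epochs > 1:
            frac = epoch / (epochs - 1)
            opt.lr = lr_min + 0.5 * (lr - lr_min) * (1 + np.cos(np.pi * frac))
        order = rng.permutation(len(dataset))
        losses = []
        for lo in range(0, len(order), batch_size):
            batch = order[lo:lo + batch_size]
            opt.zero_grad()
            for i in batch:
                s = dataset[i]
                feats = model.pooled(s.projection, s.geometry, s.cloud_ref)
                per_node = model.net(s.cloud_ref.coords, feats.features)
                # supervise the point-cloud-wise DVF against the (uniform)
                # rigid truth: every node carries the full gradient signal,
                # and the inference-time average only reduces variance
                err = per_node - s.shift_true[None]
                loss = tsum(err * err) / (3.0 * s.cloud_ref.n_nodes)
                loss.backward(np.array(1.0 / len(batch)))
                losses.append(float(loss.data))
            opt.step()
        history.append(float(np.mean(losses)))
    model.trained = True
    return model, history
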