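"""Conditional denoising diffusion over per-node liver-surface DVFs.

The forward process corrupts the normalized displacement field x0 with
Gaussian noise under a variance schedule, x_t = sqrt(a_bar_t) x0 +
sqrt(1 - a_bar_t) eps. The reverse (sampling) loop starts from pure noise
and alternates two operations: (1) apply the current intermediate DVF — re-
centered by the frozen rigid-alignment shift — to the prior reference cloud,
and pool projection features at the resulting intermediate cloud; (2) run one
ancestral denoising step with the point-voxel network conditioned on those
features. After T steps the DVF estimate is the de-normalized x0 plus the
rigid shift.

Displacements are normalized by ``scale`` (mm) after rigid-shift removal so
the diffusion variable is near zero-mean and unit-scale, which is the regime
denoising diffusion is designed for; the rigid model carries the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .core import DisplacementField, SurfacePointCloud
from .losses import (LossWeights, NeighborGraph, denoising_loss, energy_loss,
                     knn_graph, laplacian_loss, total_loss, weighted_mse)
from .nn import Adam, Module
from .pooling import (BackboneConfig, FeatureExtractor, PooledFeatures,
                      extract_feature_stack, global_features, pool_features)
from .projector import ConeBeamGeometry, ProjectionImage
from .pvcnn import PVCNNConfig, PointVoxelNet
from .rigid import RigidModel

__all__ = [
    "VarianceSchedule",
    "NoisyState",
    "DiffusionModel",
    "DiffusionSample",
    "make_schedule",
    "forward_noise",
    "denoise_step",
    "sample_dvf",
    "train_diffusion",
]


@dataclass
class VarianceSchedule:
    """beta_t, alpha_t = 1 - beta_t and their running product alpha_bar_t,
    indexed by t = 1..T (array position t-1)."""

    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.beta.ndim != 1 or self.beta.size < 1:
            raise ValueError("beta must be a nonempty 1D array")
        if np.any(self.beta < 0) or np.any(self.beta >= 1):
            raise ValueError("require 0 <= beta_t < 1")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.cumprod(self.alpha)

    @property
    def T(self) -> int:
        return self.beta.size


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear") -> VarianceSchedule:
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if not (0 <= beta_start <= beta_end < 1):
        raise ValueError("require 0 <= beta_start <= beta_end < 1")
    if T < 1:
        raise ValueError("T must be at least 1")
    return VarianceSchedule(np.linspace(beta_start, beta_end, T))


@dataclass
class NoisyState:
    x: np.ndarray  # (N, 3) in normalized DVF units
    t: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("state must be finite")
        if self.t < 0:
            raise ValueError("t must be nonnegative")


def forward_noise(x0: np.ndarray, t: int, eps: np.ndarray,
                  sched: VarianceSchedule) -> NoisyState:
    """x_t = sqrt(a_bar_t) x0 + sqrt(1 - a_bar_t) eps, exactly."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != x0.shape:
        raise ValueError("eps must match x0's shape")
    if not (1 <= t <= sched.T):
        raise ValueError(f"t must be in [1, {sched.T}]")
    ab = sched.alpha_bar[t - 1]
    return NoisyState(np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps, t)


class DiffusionModel(Module):
    """Conditional denoiser: feature extractor + timestep-aware point-voxel
    network, plus the DVF normalization scale (mm)."""

    def __init__(self, backbone: BackboneConfig, hidden: int = 32,
                 grid_res: int = 9, n_blocks: int = 2, scale_mm: float = 10.0,
                 pool_mode: str = "geometry", seed: int = 0):
        if pool_mode not in ("geometry", "global"):
            raise ValueError("pool_mode must be 'geometry' or 'global'")
        rng = np.random.default_rng(seed)
        self.extractor = FeatureExtractor(backbone, rng)
        self.net = PointVoxelNet(
            PVCNNConfig(feature_width=backbone.total_channels, hidden=hidden,
                        grid_res=grid_res, n_blocks=n_blocks, with_time=True,
                        center_input=False),
            rng)
        self.scale_mm = float(scale_mm)
        self.pool_mode = pool_mode
        self.trained = False

    def condition(self, stack, geom: ConeBeamGeometry,
                  cloud: SurfacePointCloud) -> PooledFeatures:
        if self.pool_mode == "global":
            return global_features(stack, cloud.n_nodes)
        return pool_features(stack, geom, cloud)


def denoise_step(model: DiffusionModel, state: NoisyState,
                 cond: PooledFeatures, sched: VarianceSchedule,
                 rng: np.random.Generator,
                 clip_x0: float | None = 4.0) -> NoisyState:
    """One DDPM ancestral step from t to t-1 (sigma_t^2 = beta_t).

    mu = (x_t - beta_t / sqrt(1 - a_bar_t) * eps_hat) / sqrt(alpha_t), with
    eps_hat predicted from [x_t || cond]; no noise is injected at t = 1.

    With ``clip_x0`` set (the default), mu is computed through the algebraic-
    ally equivalent posterior-mean form with the implied x0 estimate clamped
    to [-clip_x0, clip_x0] in normalized units. This bounds the compounding
    of prediction errors along short sampling chains (exposure bias) and is
    a no-op whenever the implied x0 already lies inside the clamp.
    """
    t = state.t
    if t < 1:
        raise ValueError("denoise_step requires t >= 1")
    beta = sched.beta[t - 1]
    alpha = sched.alpha[t - 1]
    ab = sched.alpha_bar[t - 1]
    eps_hat = model.net(state.x, cond.features, t=t).data
    if 1.0 - ab < 1e-12:  # no noise added up to t: the step is the identity
        mu = state.x / np.sqrt(alpha)
    elif clip_x0 is None:
        mu = (state.x - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)
    else:
        x0_hat = (state.x - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)
        x0_hat = np.clip(x0_hat, -clip_x0, clip_x0)
        ab_prev = sched.alpha_bar[t - 2] if t >= 2 else 1.0
        mu = (np.sqrt(alpha) * (1.0 - ab_prev) * state.x
              + np.sqrt(ab_prev) * beta * x0_hat) / (1.0 - ab)
    if t > 1:
        mu = mu + np.sqrt(beta) * rng.standard_normal(state.x.shape)
    return NoisyState(mu, t - 1)


def sample_dvf(model: DiffusionModel, rigid_model: RigidModel | None,
               cloud_ref: SurfacePointCloud, proj: ProjectionImage,
               geom: ConeBeamGeometry, sched: VarianceSchedule,
               seed: int = 0) -> tuple[DisplacementField, np.ndarray]:
    """Full reverse-diffusion inference from one projection.

    Returns the deformable DVF (scale * x0) and the rigid shift; the complete
    DVF is their sum. With ``rigid_model=None`` (the no-rigid ablation) the
    shift is zero and the diffusion model must absorb translations.
    """
    if not model.trained or (rigid_model is not None and not rigid_model.trained):
        raise ValueError("models must be trained before sampling")
    if rigid_model is not None:
        shift = rigid_model.predict(proj, geom, cloud_ref)
    else:
        shift = np.zeros(3)
    stack = extract_feature_stack(proj, model.extractor)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((cloud_ref.n_nodes, 3))
    state = NoisyState(x, sched.T)
    for t in range(sched.T, 0, -1):
        inter = SurfacePointCloud(cloud_ref.coords + model.scale_mm * state.x
                                  + shift)
        cond = model.condition(stack, geom, inter)
        state = denoise_step(model, state, cond, sched, rng)
    return DisplacementField(model.scale_mm * state.x), shift


@dataclass
class DiffusionSample:
    cloud_ref: SurfacePointCloud
    cloud_tar: SurfacePointCloud
    projection: ProjectionImage
    geometry: ConeBeamGeometry


def train_diffusion(dataset: list[DiffusionSample],
                    rigid_model: RigidModel | None,
                    sched: VarianceSchedule,
                    loss_weights: LossWeights | None = None,
                    steps: int = 1000, lr: float = 1e-3, seed: int = 0,
                    lr_min: float | None = None,
                    model: DiffusionModel | None = None,
                    backbone: BackboneConfig | None = None,
                    graph: NeighborGraph | None = None,
                    **model_kwargs) -> tuple[DiffusionModel, list]:
    """Train the conditional denoiser with the composite objective.

    Per step: draw a sample, a timestep and noise; normalize the residual
    displacement x0 = (X_tar - X_ref - shift) / scale using the frozen rigid
    model's shift; form x_t; pool features at the intermediate cloud built
    from x_t (mirroring the inference loop); predict eps_hat; reconstruct
    x0_hat and the predicted cloud; minimize L_total. The similarity and
    regularization losses act on the reconstructed cloud against the target
    and reference, with the neighbor graph built once on the reference cloud.

    Returns the model and a per-step history of loss components.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    weights = loss_weights or LossWeights()
    if model is None:
        model = DiffusionModel(backbone or BackboneConfig.tiny(), seed=seed,
                               **model_kwargs)
    if graph is None:
        graph = knn_graph(dataset[0].cloud_ref, k=8)
    params = model.parameters()
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed + 2)
    history = []
    for step in range(steps):
        if lr_min is not None and steps > 1:
            frac = step / (steps - 1)
            opt.lr = lr_min + 0.5 * (lr - lr_min) * (1 + np.cos(np.pi * frac))
        s = dataset[rng.integers(len(dataset))]
        if rigid_model is not None:
            shift = rigid_model.predict(s.projection, s.geometry, s.cloud_ref)
        else:
            shift = np.zeros(3)
        dvf_true = s.cloud_tar.coords - s.cloud_ref.coords
        x0 = (dvf_true - shift) / model.scale_mm
        t = int(rng.integers(1, sched.T + 1))
        eps = rng.standard_normal(x0.shape)
        state = forward_noise(x0, t, eps, sched)

        inter = SurfacePointCloud(s.cloud_ref.coords
                                  + model.scale_mm * state.x + shift)
        stack = extract_feature_stack(s.projection, model.extractor)
        cond = model.condition(stack, s.geometry, inter)
        eps_hat = model.net(state.x, cond.features, t=t)

        ab = sched.alpha_bar[t - 1]
        x0_hat = (eps_hat * (-np.sqrt(1.0 - ab)) + state.x) * (1.0 / np.sqrt(ab))
        dvf_hat = x0_hat * model.scale_mm + shift
        cloud_pred = dvf_hat + s.cloud_ref.coords

        # similarity/regularization losses are evaluated in the diffusion's
        # normalized units (mm / scale) so their magnitudes are commensurate
        # with the unit-variance denoising loss under the stated weights
        inv = 1.0 / model.scale_mm
        l_noise = denoising_loss(eps, eps_hat)
        l_sim = weighted_mse(cloud_pred * inv, s.cloud_tar.coords * inv,
                             weights.si_weight)
        l_lap = laplacian_loss(s.cloud_ref.coords * inv, cloud_pred * inv,
                               graph)
        l_eng = energy_loss(dvf_hat * inv, graph)
        # the reconstructed-cloud losses are weighted by the timestep's
        # signal-to-noise factor (clipped at 1): supervising x0_hat without it
        # amplifies the high-noise timesteps by (1-a_bar)/a_bar and destabil-
        # izes short schedules; with it the x0 supervision is commensurate
        # with the noise loss at every t
        w_t = min(1.0, ab / (1.0 - ab))
        loss = total_loss(l_noise, w_t * l_sim, w_t * l_lap, w_t * l_eng,
                          weights)

        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({
            "step": step,
            "L_noise": float(l_noise.data),
            "L_sim": float(l_sim.data),
            "L_lap": float(l_lap.data),
            "L_eng": float(l_eng.data),
            "L_total": float(loss.data),
        })
    model.trained = True
    return model, history
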