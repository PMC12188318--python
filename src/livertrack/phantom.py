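"""Synthetic anatomy, respiratory motion, and the augmentation plan.

The phantom emulates the study data this package is built for: an abdominal
attenuation volume with a liver of distinct (configurable) contrast, a liver
surface point cloud, an interior tumor point set, a low-rank respiratory
motion model (mean displacement field plus three principal components), and
an augmentation plan that expands a handful of breathing phases into
train/validation/test datasets by scaling the motion-model coefficients and
adding rigid setup shifts.

The liver is a smoothed superellipsoid; the motion components are built
analytically with a dominant superior-inferior bulk excursion, a smaller
anterior-posterior tilt, and a local bulge near the inferior tip, mimicking
the SI >> AP >> LR ordering of respiration-induced liver motion.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .core import DisplacementField, SurfacePointCloud

__all__ = [
    "PhantomConfig",
    "Phantom",
    "MotionModel",
    "PlanEntry",
    "AugmentationPlan",
    "make_phantom",
    "make_phase_dvfs",
    "build_motion_model",
    "synthesize_dvf",
    "deformation_weights",
    "make_augmentation_plan",
    "apply_dvf",
    "deform_phantom_volume",
    "true_interior_displacement",
]


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Knobs of the synthetic anatomy.

    grid/spacing define an isotropic volume centered on the isocenter.
    ``contrast`` is the liver-minus-background mean intensity difference in
    units of the background texture s.d., so it is (by construction) the
    approximate CNR of the liver against nearby soft tissue.
    """

    grid: int = 64
    spacing_mm: float = 4.0
    liver_half_axes_mm: tuple[float, float, float] = (55.0, 42.0, 72.0)
    liver_center_mm: tuple[float, float, float] = (6.0, -8.0, 4.0)
    superellipsoid_power: float = 2.5
    surface_perturb_amp: float = 0.08
    tumor_offset_mm: tuple[float, float, float] = (12.0, -6.0, -28.0)
    tumor_radius_mm: float = 10.0
    n_surface_nodes: int = 200
    n_tumor_points: int = 48
    background_mu: float = 0.020      # soft-tissue attenuation, 1/mm
    background_sigma: float = 0.0015  # texture s.d., 1/mm
    contrast: float = 2.0             # liver CNR vs background
    tumor_contrast: float = 0.6       # tumor bump, in background-sigma units
    seed: int = 0


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)],
        axis=1,
    )


class _LiverShape:
    """Smoothed superellipsoid: radius depends only on direction."""

    def __init__(self, cfg: PhantomConfig):
        rng = np.random.default_rng(cfg.seed + 101)
        self.center = np.asarray(cfg.liver_center_mm, dtype=np.float64)
        self.half_axes = np.asarray(cfg.liver_half_axes_mm, dtype=np.float64)
        self.power = cfg.superellipsoid_power
        self.amp = cfg.surface_perturb_amp
        self.lobe_dirs = _normalize(rng.normal(size=(4, 3)))
        self.lobe_coefs = rng.uniform(-1.0, 1.0, size=4)

    def radius(self, directions: np.ndarray) -> np.ndarray:
        """Surface radius (mm) along unit directions, shape (N,)."""
        d = np.atleast_2d(directions)
        p = self.power
        base = np.sum(np.abs(d / self.half_axes) ** p, axis=1) ** (-1.0 / p)
        lobes = (d @ self.lobe_dirs.T) ** 2 - 1.0 / 3.0  # zero-mean bumps
        return base * (1.0 + self.amp * (lobes @ self.lobe_coefs))

    def normalized_radius(self, points_mm: np.ndarray) -> np.ndarray:
        """|p - c| / surface radius; <= 1 means inside (0 at the center)."""
        rel = np.atleast_2d(points_mm) - self.center
        r = np.linalg.norm(rel, axis=1)
        safe = np.where(r > 1e-12, r, 1.0)
        dirs = rel / safe[:, None]
        rho = r / self.radius(dirs)
        return np.where(r > 1e-12, rho, 0.0)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


@dataclass
class Phantom:
    """Synthetic abdominal anatomy in a cube of isotropic voxels."""

    volume: np.ndarray            # (n, n, n) attenuation, 1/mm
    spacing_mm: float
    origin_mm: np.ndarray         # position of voxel (0,0,0) center
    liver_cloud: SurfacePointCloud
    tumor_points: np.ndarray      # (M, 3) mm, strictly inside the liver
    liver_label: np.ndarray       # binary mask, same shape as volume
    config: PhantomConfig
    shape: _LiverShape = field(repr=False, default=None)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.volume.shape[0]
        ax = self.origin_mm[0] + self.spacing_mm * np.arange(n)
        ay = self.origin_mm[1] + self.spacing_mm * np.arange(n)
        az = self.origin_mm[2] + self.spacing_mm * np.arange(n)
        return ax, ay, az


def make_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the synthetic phantom. Deterministic given ``config.seed``."""
    cfg = config or PhantomConfig()
    if cfg.grid < 16:
        raise ValueError("grid must be at least 16 voxels per side")
    shape = _LiverShape(cfg)
    rng = np.random.default_rng(cfg.seed)

    n, sp = cfg.grid, cfg.spacing_mm
    origin = -0.5 * (n - 1) * sp * np.ones(3)
    ax = origin[0] + sp * np.arange(n)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    # soft-tissue texture: a smooth low-frequency component (gives the DRRs
    # gradients) plus a dominant voxel-wise component (so a small ROI's s.d.
    # approximates the global background sigma and CNR ~ contrast)
    from scipy.ndimage import zoom

    coarse = rng.normal(size=(8, 8, 8))
    smooth = zoom(coarse, n / 8.0, order=3)[:n, :n, :n]
    smooth /= max(smooth.std(), 1e-12)
    grain = rng.normal(size=(n, n, n))
    texture = cfg.background_sigma * (0.35 * smooth + np.sqrt(1 - 0.35**2) * grain)

    body_half = 0.47 * n * sp * np.array([1.0, 0.92, 1.05])
    body = (np.sum((pts / body_half) ** 2, axis=1) <= 1.0).reshape(n, n, n)

    rho = shape.normalized_radius(pts).reshape(n, n, n)
    liver = (rho <= 1.0) & body

    tumor_center = shape.center + np.asarray(cfg.tumor_offset_mm)
    # containment: every point of the tumor sphere must be strictly inside
    probe = tumor_center + cfg.tumor_radius_mm * _fibonacci_directions(96)
    if np.any(shape.normalized_radius(probe) >= 1.0 - 0.5 * sp / np.mean(shape.half_axes)):
        raise ValueError("tumor does not fit inside the liver")
    tumor_mask = (np.linalg.norm(pts - tumor_center, axis=1)
                  <= cfg.tumor_radius_mm).reshape(n, n, n)

    volume = cfg.background_mu + texture
    volume[liver] += cfg.contrast * cfg.background_sigma
    volume[tumor_mask] += cfg.tumor_contrast * cfg.background_sigma
    volume[~body] = 0.0
    volume = np.clip(volume, 0.0, None)

    dirs = _fibonacci_directions(cfg.n_surface_nodes)
    cloud = SurfacePointCloud(shape.center + shape.radius(dirs)[:, None] * dirs)

    # tumor point set: center plus two deterministic shells
    m = cfg.n_tumor_points
    n_outer = max(m * 2 // 3, 4)
    n_inner = max(m - n_outer - 1, 3)
    tumor_points = np.vstack([
        tumor_center,
        tumor_center + 0.55 * cfg.tumor_radius_mm * _fibonacci_directions(n_inner),
        tumor_center + 0.95 * cfg.tumor_radius_mm * _fibonacci_directions(n_outer),
    ])

    return Phantom(volume=volume, spacing_mm=sp, origin_mm=origin,
                   liver_cloud=cloud, tumor_points=tumor_points,
                   liver_label=liver.astype(np.uint8), config=cfg, shape=shape)


# ---------------------------------------------------------------------------
# Respiratory motion model
# ---------------------------------------------------------------------------


def _motion_basis(cloud: SurfacePointCloud, shape: _LiverShape) -> np.ndarray:
    """Three analytic motion fields (3, N, 3), SI >> AP >> LR in magnitude."""
    p = cloud.coords
    c = shape.center
    zr = shape.half_axes[2]
    z_hat = np.clip((p[:, 2] - c[2]) / zr, -1.2, 1.2)

    n = p.shape[0]
    b1 = np.zeros((n, 3))  # dominant SI bulk excursion, slightly graded in z
    b1[:, 2] = -2.2 * (1.0 + 0.25 * z_hat)
    b1[:, 1] = 0.35
    b1[:, 0] = 0.12

    b2 = np.zeros((n, 3))  # AP tilt about the LR axis
    b2[:, 1] = 1.1 * z_hat
    b2[:, 2] = -0.30 * z_hat
    b2[:, 0] = 0.05 * z_hat

    pole = c + np.array([0.0, 0.0, -shape.half_axes[2]])
    g = np.exp(-np.sum((p - pole) ** 2, axis=1) / (2.0 * 28.0**2))
    out = _normalize(p - c + 1e-9)
    b3 = 0.9 * g[:, None] * out  # local bulge near the inferior tip

    return np.stack([b1, b2, b3])


def make_phase_dvfs(phantom: Phantom, n_phases: int = 10) -> list[DisplacementField]:
    """Per-node DVFs of a breathing cycle (phase 0 = reference, near zero).

    The cycle drives the three analytic motion components with phase-shifted
    raised-cosine curves, introducing the mild hysteresis seen in real
    breathing traces.
    """
    basis = _motion_basis(phantom.liver_cloud, phantom.shape)
    theta = 2.0 * np.pi * np.arange(n_phases) / n_phases
    c1 = 1.8 * 0.5 * (1.0 - np.cos(theta))
    c2 = 1.2 * 0.5 * (1.0 - np.cos(theta - 0.7)) - 1.2 * 0.5 * (1.0 - np.cos(-0.7))
    c3 = 0.6 * np.sin(2.0 * theta) + 0.2 * np.sin(theta)  # second harmonic
    return [
        DisplacementField(c1[t] * basis[0] + c2[t] * basis[1] + c3[t] * basis[2])
        for t in range(n_phases)
    ]


@dataclass
class MotionModel:
    """Mean DVF plus principal motion components (PCA of phase DVFs)."""

    mean: np.ndarray            # (N, 3)
    components: np.ndarray      # (n_components, N, 3), unit flattened norm
    singular_values: np.ndarray
    phase_weights: np.ndarray   # (n_phases, n_components) PCA scores

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def build_motion_model(phase_dvfs: list[DisplacementField],
                       n_components: int = 3) -> MotionModel:
    """PCA of per-node phase DVFs: arithmetic mean + top principal directions.

    Component signs are fixed so the largest-magnitude entry of each is
    positive, making the decomposition reproducible.
    """
    if len(phase_dvfs) < n_components + 1:
        raise ValueError("need at least n_components + 1 phases")
    shape = phase_dvfs[0].vectors.shape
    X = np.stack([d.vectors.reshape(-1) for d in phase_dvfs])  # (P, 3N)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:n_components].copy()
    for i in range(n_components):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = Xc @ comps.T
    return MotionModel(
        mean=mean.reshape(shape),
        components=comps.reshape(n_components, *shape),
        singular_values=s[:n_components].copy(),
        phase_weights=scores,
    )


def synthesize_dvf(model: MotionModel, weights) -> DisplacementField:
    """Exact linear combination ``w0 * mean + sum_i w_i * component_i``."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (1 + model.n_components,):
        raise ValueError(
            f"expected {1 + model.n_components} weights, got {w.shape}")
    out = w[0] * model.mean
    for i in range(model.n_components):
        out = out + w[1 + i] * model.components[i]
    return DisplacementField(out)


def deformation_weights(model: MotionModel, entry: "PlanEntry") -> np.ndarray:
    """Map a plan entry's scale factors to synthesize_dvf weights.

    The factors scale the motion-model coefficients of the entry's phase:
    ``w0 = s0`` for the mean and ``w_i = s_i * score_i(phase)`` for the
    principal components.
    """
    phase_idx = entry.phase // 10
    scores = model.phase_weights[phase_idx]
    s = np.asarray(entry.scales, dtype=np.float64)
    return np.concatenate([[s[0]], s[1:1 + model.n_components]
                           * scores[: model.n_components]])


# ---------------------------------------------------------------------------
# Augmentation plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanEntry:
    phase: int                 # respiratory phase label (percent)
    scales: tuple              # coefficient scale factors (s0, s1, s2, s3)
    translation: tuple         # rigid setup shift, mm (LR, AP, SI)
    split: str                 # train | val | test
    deformation_id: int


@dataclass
class AugmentationPlan:
    entries: list

    def volumes(self, split: str | None = None) -> list:
        if split is None:
            return list(self.entries)
        return [e for e in self.entries if e.split == split]

    def n_volumes(self, split: str | None = None) -> int:
        return len(self.volumes(split))

    def deformations(self, split: str | None = None) -> list:
        seen, out = set(), []
        for e in self.volumes(split):
            if e.deformation_id not in seen:
                seen.add(e.deformation_id)
                out.append(e)
        return out

    def n_deformations(self, split: str | None = None) -> int:
        return len(self.deformations(split))

    def to_json(self, path) -> None:
        payload = [
            {"phase": e.phase, "scales": list(e.scales),
             "translation": list(e.translation), "split": e.split,
             "deformation_id": e.deformation_id}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AugmentationPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([
            PlanEntry(phase=d["phase"], scales=tuple(d["scales"]),
                      translation=tuple(d["translation"]), split=d["split"],
                      deformation_id=d["deformation_id"])
            for d in payload
        ])


#: coefficient scale-factor ranges and per-coefficient sample counts used to
#: expand each training/validation phase (Cartesian product 4*6*4*2 = 192)
TRAINVAL_RANGES = ((0.95, 1.05), (-1.5, 3.0), (-1.5, 3.0), (-1.5, 1.5))
TRAINVAL_SAMPLES = (4, 6, 4, 2)
TEST_RANGES = ((1.0, 1.0), (0.0, 4.0), (0.0, 4.0), (0.0, 2.0))
TRAINVAL_SHIFT_MM = (-6.0, 6.0)
TEST_SHIFT_MM = (0.0, 10.0)
N_TEST_COMBOS = 15
N_SHIFTS_PER_DEFORMATION = 3


def make_augmentation_plan(
    seed: int = 0,
    trainval_phases: tuple = (10, 20, 30, 40, 70, 80),
    test_phases: tuple = (50, 60, 90),
    trainval_ranges: tuple = TRAINVAL_RANGES,
    trainval_samples: tuple = TRAINVAL_SAMPLES,
    test_ranges: tuple = TEST_RANGES,
    trainval_shift_mm: tuple = TRAINVAL_SHIFT_MM,
    test_shift_mm: tuple = TEST_SHIFT_MM,
    n_test_combos: int = N_TEST_COMBOS,
) -> AugmentationPlan:
    """Build the dataset expansion plan.

    Train/val: for each phase, per-coefficient uniform draws (4, 6, 4, 2 by
    default) combined as a Cartesian product into 192 deformations, randomly
    assigned 2:1 to train:val; each deformation yields one untranslated volume
    plus three randomly translated ones. Test: per phase, ``n_test_combos``
    coefficient combinations, each yielding three translated volumes only
    (the zero-shift volume is discarded so every test case carries both
    deformable and rigid motion).

    Counts are exact and seed-independent; only the drawn values vary.
    """
    for rng_pair in tuple(trainval_ranges) + tuple(test_ranges):
        lo, hi = rng_pair
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"malformed coefficient range {rng_pair!r}")
    for lo, hi in (trainval_shift_mm, test_shift_mm):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("malformed translation range")
    if len(trainval_samples) != len(trainval_ranges):
        raise ValueError("one sample count per coefficient is required")

    rng = np.random.default_rng(seed)
    entries: list[PlanEntry] = []
    deformation_id = 0

    for phase in trainval_phases:
        draws = [np.sort(rng.uniform(lo, hi, size=k))
                 for (lo, hi), k in zip(trainval_ranges, trainval_samples)]
        combos = list(itertools.product(*draws))
        n_val = len(combos) // 3
        order = rng.permutation(len(combos))
        val_ids = set(order[:n_val].tolist())
        for i, scales in enumerate(combos):
            split = "val" if i in val_ids else "train"
            shifts = [np.zeros(3)] + [
                rng.uniform(*trainval_shift_mm, size=3)
                for _ in range(N_SHIFTS_PER_DEFORMATION)
            ]
            for sh in shifts:
                entries.append(PlanEntry(phase=phase, scales=tuple(scales),
                                         translation=tuple(sh), split=split,
                                         deformation_id=deformation_id))
            deformation_id += 1

    for phase in test_phases:
        for _ in range(n_test_combos):
            scales = tuple(rng.uniform(lo, hi) for lo, hi in test_ranges)
            for _ in range(N_SHIFTS_PER_DEFORMATION):
                sh = rng.uniform(*test_shift_mm, size=3)
                entries.append(PlanEntry(phase=phase, scales=scales,
                                         translation=tuple(sh), split="test",
                                         deformation_id=deformation_id))
            deformation_id += 1

    return AugmentationPlan(entries)


def apply_dvf(cloud: SurfacePointCloud, dvf: DisplacementField,
              shift=(0.0, 0.0, 0.0)) -> SurfacePointCloud:
    """Move every node: coords + dvf + shift, preserving node order."""
    if dvf.n_nodes != cloud.n_nodes:
        raise ValueError("DVF and cloud node counts differ")
    return SurfacePointCloud(cloud.coords + dvf.vectors
                             + np.asarray(shift, dtype=np.float64))


# ---------------------------------------------------------------------------
# Dense rendering of deformed anatomy
# ---------------------------------------------------------------------------


def _falloff(rho: np.ndarray, inner: float = 1.0, outer: float = 1.6) -> np.ndarray:
    """1 inside the liver, cosine taper to 0 by ``outer`` normalized radius."""
    t = np.clip((rho - inner) / (outer - inner), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def true_interior_displacement(phantom: Phantom, surface_dvf: DisplacementField,
                               shift, points_mm: np.ndarray) -> np.ndarray:
    """Ground-truth displacement of interior points in the synthetic world.

    The synthetic anatomy's deformation is *defined* as the smooth scattered-
    data extension of the surface DVF (see :mod:`livertrack.propagate`) plus
    the rigid setup shift, tapered to shift-only outside the liver.
    """
    from .propagate import interpolate_interior

    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    interior = interpolate_interior(phantom.liver_cloud, surface_dvf, pts)
    rho = phantom.shape.normalized_radius(pts)
    return _falloff(rho)[:, None] * interior.vectors + np.asarray(shift)


def deform_phantom_volume(phantom: Phantom, surface_dvf: DisplacementField,
                          shift=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Render the deformed attenuation volume by inverse warping.

    Uses the first-order inverse of the forward displacement field (adequate
    for respiratory-scale motion at the phantom's voxel size): the voxel at x
    samples the reference at x - d(x).
    """
    from scipy.ndimage import map_coordinates

    n = phantom.volume.shape[0]
    sp, origin = phantom.spacing_mm, phantom.origin_mm
    ax = origin[0] + sp * np.arange(n)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    disp = np.tile(np.asarray(shift, dtype=np.float64), (pts.shape[0], 1))
    rho = phantom.shape.normalized_radius(pts)
    near = rho < 1.6
    if np.any(near):
        from .propagate import interpolate_interior

        interior = interpolate_interior(phantom.liver_cloud, surface_dvf,
                                        pts[near])
        disp[near] += _falloff(rho[near])[:, None] * interior.vectors

    src = (pts - disp - origin) / sp
    warped = map_coordinates(phantom.volume, src.T, order=1, mode="nearest")
    return warped.reshape(phantom.volume.shape)
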