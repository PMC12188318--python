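"""Cone-beam projection geometry, DRR rendering, detector noise, and CNR.

Conventions (used consistently by this module and the feature pooling layer):

* the gantry rotates about the patient SI axis (z); at gantry 0 the x-ray
  source sits on the +AP axis at ``source_to_axis_mm`` from the isocenter;
* detector pixel coordinates are continuous, with (0, 0) at the *center* of
  the corner pixel; column index u grows along the detector's +LR direction
  (at gantry 0) and row index v along +SI;
* projections hold line integrals of attenuation (dimensionless); the noise
  stage converts to photon counts and back.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = [
    "ConeBeamGeometry",
    "ProjectionImage",
    "RoiSpec",
    "project_points",
    "simulate_drr",
    "add_noise",
    "compute_cnr",
]


@dataclass
class ConeBeamGeometry:
    gantry_angle_deg: float = 0.0
    source_to_axis_mm: float = 1000.0
    source_to_detector_mm: float = 1500.0
    detector_cols: int = 512
    detector_rows: int = 384
    pixel_pitch_mm: float = 0.776

    def __post_init__(self):
        if not (self.source_to_detector_mm > self.source_to_axis_mm > 0):
            raise ValueError("require SDD > SAD > 0")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.detector_cols < 2 or self.detector_rows < 2:
            raise ValueError("detector must be at least 2x2 pixels")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_axis_mm

    def with_angle(self, angle_deg: float) -> "ConeBeamGeometry":
        d = asdict(self)
        d["gantry_angle_deg"] = float(angle_deg)
        return ConeBeamGeometry(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "ConeBeamGeometry":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ProjectionImage:
    pixels: np.ndarray            # (rows, cols) line integrals
    geometry: ConeBeamGeometry

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.geometry.detector_rows,
                                 self.geometry.detector_cols):
            raise ValueError("pixel array does not match the geometry")


@dataclass
class RoiSpec:
    center_mm: tuple
    radius_mm: float
    role: str = "target"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")


def _rot_z(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def project_points(geom: ConeBeamGeometry,
                   points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Perspective-project 3D points (mm) to continuous detector pixel coords.

    Returns ``(uv, valid)`` where ``uv[:, 0]`` is the column and ``uv[:, 1]``
    the row coordinate. Points at or behind the source plane are flagged
    invalid (their coordinates are set to NaN), as are points falling outside
    the detector.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    p = pts @ _rot_z(-geom.gantry_angle_deg).T  # into the source frame
    depth = geom.source_to_axis_mm - p[:, 1]    # distance from source plane
    ok = depth > 1e-9
    safe = np.where(ok, depth, 1.0)
    u_mm = p[:, 0] * geom.source_to_detector_mm / safe
    v_mm = p[:, 2] * geom.source_to_detector_mm / safe
    u = u_mm / geom.pixel_pitch_mm + 0.5 * (geom.detector_cols - 1)
    v = v_mm / geom.pixel_pitch_mm + 0.5 * (geom.detector_rows - 1)
    valid = (ok & (u >= 0.0) & (u <= geom.detector_cols - 1)
             & (v >= 0.0) & (v <= geom.detector_rows - 1))
    uv = np.stack([u, v], axis=1)
    uv[~ok] = np.nan
    return uv, valid


def _source_and_pixels(geom: ConeBeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Source position and all detector pixel centers in the patient frame."""
    R = _rot_z(geom.gantry_angle_deg)
    source = R @ np.array([0.0, geom.source_to_axis_mm, 0.0])
    cols = np.arange(geom.detector_cols)
    rows = np.arange(geom.detector_rows)
    u_mm = (cols - 0.5 * (geom.detector_cols - 1)) * geom.pixel_pitch_mm
    v_mm = (rows - 0.5 * (geom.detector_rows - 1)) * geom.pixel_pitch_mm
    uu, vv = np.meshgrid(u_mm, v_mm)  # (rows, cols)
    y = geom.source_to_axis_mm - geom.source_to_detector_mm
    pix = np.stack([uu, np.full_like(uu, y), vv], axis=-1).reshape(-1, 3)
    return source, pix @ R.T


def simulate_drr(volume: np.ndarray, geom: ConeBeamGeometry,
                 spacing_mm: float, origin_mm=None,
                 step_fraction: float = 0.5) -> ProjectionImage:
    """Digitally reconstructed radiograph: per-pixel line integrals.

    Rays march from the source through each pixel center with a step of
    ``step_fraction`` voxels (<= 0.5 by default) and trilinear sampling.
    Rays that miss the volume integrate to zero.
    """
    from scipy.ndimage import map_coordinates

    vol = np.asarray(volume, dtype=np.float64)
    if origin_mm is None:
        origin_mm = -0.5 * (np.asarray(vol.shape) - 1) * spacing_mm
    origin_mm = np.asarray(origin_mm, dtype=np.float64)

    source, pix = _source_and_pixels(geom)
    d = pix - source  # ray directions, |d| spans source->pixel

    # slab intersection with the interpolation support: trilinear sampling
    # with zero padding ramps to zero one full voxel beyond the edge centers
    lo = origin_mm - spacing_mm
    hi = origin_mm + np.asarray(vol.shape) * spacing_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - source) / d
        t2 = (hi - source) / d
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    tmin = np.clip(tmin, 0.0, None)
    hit = tmax > tmin

    npix = pix.shape[0]
    out = np.zeros(npix)
    if np.any(hit):
        seg_mm = (tmax - tmin) * np.linalg.norm(d, axis=1)
        n_steps = int(np.ceil(seg_mm[hit].max() / (step_fraction * spacing_mm)))
        n_steps = max(n_steps, 2)
        frac = (np.arange(n_steps) + 0.5) / n_steps
        th = tmin[hit][:, None] + (tmax - tmin)[hit][:, None] * frac[None, :]
        pos = source + th[..., None] * d[hit][:, None, :]  # (nhit, n_steps, 3)
        idx = (pos - origin_mm) / spacing_mm
        # grid-constant: attenuation ramps linearly to zero across the
        # half-voxel boundary band, consistent with the bbox used above
        samples = map_coordinates(vol, idx.reshape(-1, 3).T, order=1,
                                  mode="grid-constant", cval=0.0)
        dl = seg_mm[hit] / n_steps
        out[hit] = samples.reshape(-1, n_steps).sum(axis=1) * dl
    return ProjectionImage(out.reshape(geom.detector_rows, geom.detector_cols),
                           geom)


def add_noise(proj: ProjectionImage, photons_mean: float,
              electronic_sigma: float = 10.0, seed: int | None = None,
              noiseless: bool = False) -> ProjectionImage:
    """Quantum + electronic detector noise in the photon-count domain.

    counts = Poisson(photons_mean * exp(-g)) + Normal(0, electronic_sigma),
    clamped at >= 1, then mapped back to line integrals
    ``-log(counts / photons_mean)``. Deterministic per seed.
    """
    if noiseless:
        return ProjectionImage(proj.pixels.copy(), proj.geometry)
    if photons_mean <= 0:
        raise ValueError("photons_mean must be positive")
    rng = np.random.default_rng(seed)
    expected = photons_mean * np.exp(-proj.pixels)
    counts = rng.poisson(expected).astype(np.float64)
    if electronic_sigma > 0:
        counts += rng.normal(0.0, electronic_sigma, size=counts.shape)
    counts = np.maximum(counts, 1.0)
    return ProjectionImage(-np.log(counts / photons_mean), proj.geometry)


def compute_cnr(volume: np.ndarray, spacing_mm: float, origin_mm,
                target: RoiSpec, background: RoiSpec) -> float:
    """Contrast-to-noise ratio between two spherical ROIs.

    CNR = (mean(target) - mean(background)) / sd(background), over voxels
    whose centers fall inside each sphere.
    """
    vol = np.asarray(volume, dtype=np.float64)
    origin_mm = np.asarray(origin_mm, dtype=np.float64)
    n = vol.shape
    ax = [origin_mm[i] + spacing_mm * np.arange(n[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)

    def roi_values(spec: RoiSpec) -> np.ndarray:
        c = np.asarray(spec.center_mm, dtype=np.float64)
        mask = np.sum((pts - c) ** 2, axis=-1) <= spec.radius_mm**2
        vals = vol[mask]
        if vals.size == 0:
            raise ValueError(f"{spec.role} ROI contains no voxel centers")
        return vals

    tgt = roi_values(target)
    bkg = roi_values(background)
    sd = bkg.std()
    if sd == 0:
        raise ValueError("background ROI has zero standard deviation")
    return float((tgt.mean() - bkg.mean()) / sd)
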