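"""Boundary-to-interior motion propagation for tumor localization.

The estimated liver-surface displacement field is decomposed into a spatially
uniform (DC) part, representing rigid-like motion, and a residual oscillating
(AC) part. The AC part is extended into the liver interior and the DC part is
added back afterwards.

The interior extension here is a deterministic thin-plate-spline (polyharmonic
r kernel with affine terms) scattered-data interpolant fitted per axis to the
surface nodes. It is a synthetic stand-in for a learned biomechanical model:
the interface (surface DVF in, interior displacements out, AC-only input)
is kept so a finite-element-trained backend can be swapped in without
touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .core import DisplacementField, SurfacePointCloud

__all__ = ["InteriorField", "decompose_dvf", "interpolate_interior",
           "localize_tumor"]


@dataclass
class InteriorField:
    """Displacement 3-vectors (mm) at queried interior locations."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("interior displacements must be finite")


def decompose_dvf(dvf: DisplacementField) -> tuple[np.ndarray, DisplacementField]:
    """Split a DVF into its per-axis mean (DC) and residual (AC); DC + AC
    reconstructs the input exactly."""
    if dvf.n_nodes == 0:
        raise ValueError("empty DVF")
    dc = dvf.vectors.mean(axis=0)
    return dc, DisplacementField(dvf.vectors - dc)


def interpolate_interior(surface_cloud: SurfacePointCloud,
                         surface_dvf: DisplacementField,
                         query_points_mm: np.ndarray,
                         smoothing: float = 1e-6) -> InteriorField:
    """Thin-plate-spline extension of a surface DVF to interior points.

    Fits a polyharmonic (r) kernel with degree-1 polynomial terms to the AC
    component per axis, evaluates at the queries, and re-adds the DC
    component. Exactly reproduces affine surface fields (up to the
    regularization tolerance) and interpolates the surface DVF at the nodes.
    """
    if surface_dvf.n_nodes != surface_cloud.n_nodes:
        raise ValueError("surface DVF and cloud node counts differ")
    coords = surface_cloud.coords
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise ValueError("surface nodes are degenerate (coplanar or worse)")
    dc, ac = decompose_dvf(surface_dvf)
    rbf = RBFInterpolator(coords, ac.vectors, kernel="linear", degree=1,
                          smoothing=smoothing)
    queries = np.atleast_2d(np.asarray(query_points_mm, dtype=np.float64))
    return InteriorField(rbf(queries) + dc)


def localize_tumor(phantom, predicted_surface_dvf: DisplacementField,
                   rigid_shift) -> np.ndarray:
    """Predicted tumor point set: prior points moved by the interior field
    plus the rigid shift."""
    pts = phantom.tumor_points
    lo = phantom.liver_cloud.coords.min(axis=0) - 1e-9
    hi = phantom.liver_cloud.coords.max(axis=0) + 1e-9
    if np.any(pts < lo) or np.any(pts > hi):
        raise ValueError("tumor points fall outside the liver bounding volume")
    field = interpolate_interior(phantom.liver_cloud, predicted_surface_dvf, pts)
    return pts + field.vectors + np.asarray(rigid_shift, dtype=np.float64)
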