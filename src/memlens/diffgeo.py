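"""Differential geometry on height fields.

Curvatures are computed from central finite differences of z(x, y):

    H = [(1 + z_x^2) z_yy - 2 z_x z_y z_xy + (1 + z_y^2) z_xx]
        / [2 (1 + z_x^2 + z_y^2)^(3/2)]
    K = (z_xx z_yy - z_xy^2) / (1 + z_x^2 + z_y^2)^2

with the surface normal oriented toward +z (the cytosolic side), so a bulge
toward +z has negative mean curvature at its apex. A regional radius of
curvature is obtained by inverting the region-averaged H, and a sphere can
be fit directly to 3-D points (algebraic least squares refined by
Gauss-Newton) for free-floating patches such as a bicelle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .surfaces import GridSpec, HeightField


@dataclass
class ScalarMap:
    """A per-grid-cell derived quantity (curvature 1/A, thickness A, ...)."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ParameterError("values shape does not match grid")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.values = np.where(self.valid, self.values, np.nan)


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


def _gradients(field: HeightField):
    z = field.z
    h = field.grid.spacing
    zx, zy = np.gradient(z, h, h, edge_order=1)
    zxx, zxy = np.gradient(zx, h, h, edge_order=1)
    _, zyy = np.gradient(zy, h, h, edge_order=1)
    return zx, zy, zxx, zxy, zyy


def _check_region(field: HeightField) -> None:
    # need at least a 3x3 valid block for central differences to mean anything
    v = field.valid
    ok = (v[:-2, :-2] & v[1:-1, :-2] & v[2:, :-2]
          & v[:-2, 1:-1] & v[1:-1, 1:-1] & v[2:, 1:-1]
          & v[:-2, 2:] & v[1:-1, 2:] & v[2:, 2:])
    if not ok.any():
        raise GeometryError("valid region smaller than 3x3 cells")


def mean_curvature_map(field: HeightField) -> ScalarMap:
    """Mean curvature H of the height field, in 1/Angstrom."""
    _check_region(field)
    zx, zy, zxx, zxy, zyy = _gradients(field)
    num = (1 + zx ** 2) * zyy - 2 * zx * zy * zxy + (1 + zy ** 2) * zxx
    den = 2 * (1 + zx ** 2 + zy ** 2) ** 1.5
    return ScalarMap(field.grid, num / den, units="1/A")


def gaussian_curvature_map(field: HeightField) -> ScalarMap:
    """Gaussian curvature K of the height field, in 1/Angstrom^2."""
    _check_region(field)
    zx, zy, zxx, zxy, zyy = _gradients(field)
    K = (zxx * zyy - zxy ** 2) / (1 + zx ** 2 + zy ** 2) ** 2
    return ScalarMap(field.grid, K, units="1/A^2")


def region_mask(grid: GridSpec, center=None, radius: float = None,
                invert: bool = False) -> np.ndarray:
    """Boolean lateral mask: a disk around ``center`` (or everything)."""
    if center is None or radius is None:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        gx, gy = grid.meshgrid()
        mask = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= radius ** 2
    return ~mask if invert else mask


def radius_of_curvature(cmap: ScalarMap, region: np.ndarray = None,
                        center=None, radius: float = None,
                        invert: bool = False):
    """Radius of curvature of a region: R = 1 / |mean H over the region|.

    The region is a boolean mask, or a disk given by ``center``/``radius``
    (``invert=True`` selects the complement — the far field). Returns
    ``(R, mean_H)``; R is ``inf`` when the region-mean curvature vanishes.
    """
    if region is None:
        region = region_mask(cmap.grid, center, radius, invert)
    sel = region & cmap.valid
    if not sel.any():
        raise GeometryError("region contains no valid cells")
    mean_h = float(np.mean(cmap.values[sel]))
    r = np.inf if mean_h == 0 else 1.0 / abs(mean_h)
    return r, mean_h


def fit_sphere(points) -> SphereFit:
    """Least-squares sphere through 3-D points.

    Algebraic (Coope) linear solve for center and radius, refined by one
    Gauss-Newton pass on the geometric residuals |p - c| - R.
    """
    if isinstance(points, HeightField):
        p = points.sample_points()
    else:
        p = np.asarray(getattr(points, "coords", points), dtype=float)
    p = p.reshape(-1, 3)
    if len(p) < 4:
        raise GeometryError("sphere fit needs >= 4 points")
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise GeometryError("points are coplanar; sphere fit is degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("degenerate sphere fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    # one Gauss-Newton pass on r_i = |p - c| - R
    diff = p - center
    d = np.linalg.norm(diff, axis=1)
    if np.any(d == 0):
        d = np.maximum(d, 1e-12)
    J = np.column_stack([-diff / d[:, None], -np.ones(len(p))])
    resid = d - radius
    step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
    center = center + step[:3]
    radius = float(radius + step[3])
    if radius <= 0:
        raise GeometryError("degenerate sphere fit (non-positive radius)")
    d = np.linalg.norm(p - center, axis=1)
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return SphereFit(center, radius, rms)
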