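"""Scattered leaflet points -> smooth continuous height fields.

The canonical two-step reconstruction: piecewise-linear interpolation over
the Delaunay triangulation of the lateral (x, y) positions onto a regular
grid, followed by LOESS local regression (tricube-weighted local polynomial
fits over a fixed fraction of nearest points) to remove the discreteness of
the sampled coordinates. Default LOESS settings are a 20% span with
quadratic local polynomials.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError, cKDTree

from .errors import GeometryError, ParameterError, SelectionError
from .io import LeafletPointCloud, LipidTrajectory

logger = logging.getLogger(__name__)

#: nodes whose degree-2 normal matrix exceeds this condition number fall
#: back to a linear local fit (and are invalidated if that also fails)
CONDITION_LIMIT = 1e10


@dataclass(frozen=True)
class GridSpec:
    """A regular lateral grid: nodes at x_range[0] + i*spacing, etc."""

    x_range: tuple
    y_range: tuple
    spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be positive")
        if (self.x_range[1] <= self.x_range[0]
                or self.y_range[1] <= self.y_range[0]):
            raise ParameterError("grid ranges must be non-degenerate")

    @classmethod
    def from_extent(cls, extent: float, spacing: float = 4.0,
                    margin: float = 0.0) -> "GridSpec":
        h = extent / 2 - margin
        return cls((-h, h), (-h, h), spacing)

    @classmethod
    def from_points(cls, xy: np.ndarray, spacing: float = 4.0,
                    margin: float = 0.0) -> "GridSpec":
        lo = xy.min(axis=0) + margin
        hi = xy.max(axis=0) - margin
        return cls((lo[0], hi[0]), (lo[1], hi[1]), spacing)

    @property
    def x(self) -> np.ndarray:
        n = int(np.floor((self.x_range[1] - self.x_range[0]) / self.spacing
                         + 1e-9)) + 1
        return self.x_range[0] + self.spacing * np.arange(n)

    @property
    def y(self) -> np.ndarray:
        n = int(np.floor((self.y_range[1] - self.y_range[0]) / self.spacing
                         + 1e-9)) + 1
        return self.y_range[0] + self.spacing * np.arange(n)

    @property
    def shape(self) -> tuple:
        return len(self.x), len(self.y)

    def meshgrid(self):
        return np.meshgrid(self.x, self.y, indexing="ij")

    def nodes(self) -> np.ndarray:
        gx, gy = self.meshgrid()
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class HeightField:
    """Surface heights z(x, y) on a :class:`GridSpec`; invalid cells are NaN."""

    grid: GridSpec
    z: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != self.grid.shape:
            raise ParameterError(
                f"z shape {self.z.shape} != grid shape {self.grid.shape}")
        if self.valid is None:
            self.valid = np.isfinite(self.z)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.z = np.where(self.valid, self.z, np.nan)

    def sample_points(self) -> np.ndarray:
        """Valid nodes as an (M, 3) array — the gridded surface samples."""
        gx, gy = self.grid.meshgrid()
        m = self.valid
        return np.column_stack([gx[m], gy[m], self.z[m]])

    def resample(self, grid: GridSpec) -> "HeightField":
        """Bilinear resampling onto another grid (NaN outside valid data)."""
        interp = RegularGridInterpolator(
            (self.grid.x, self.grid.y), self.z, method="linear",
            bounds_error=False, fill_value=np.nan)
        z = interp(grid.nodes()).reshape(grid.shape)
        return HeightField(grid, z)


@dataclass
class LoessConfig:
    """LOESS settings: fraction of points per local fit, polynomial degree,
    tricube weight kernel, optional bisquare robustness iterations."""

    span_fraction: float = 0.20
    degree: int = 2
    weight_kernel: str = "tricube"
    robustness_iters: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.span_fraction <= 1):
            raise ParameterError("span_fraction must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ParameterError("degree must be 1 or 2")
        if self.weight_kernel != "tricube":
            raise ParameterError("only the tricube kernel is supported")


# ---------------------------------------------------------------------------
# step 1: Delaunay-based scattered interpolation
# ---------------------------------------------------------------------------

def interpolate_scattered(points: LeafletPointCloud,
                          grid: GridSpec) -> HeightField:
    """Piecewise-linear interpolation of z over the Delaunay triangulation
    of the lateral positions; nodes outside the convex hull are invalid."""
    try:
        interp = LinearNDInterpolator(points.xy, points.z)
    except QhullError as exc:
        raise GeometryError(
            f"cannot triangulate lateral positions (collinear?): {exc}"
        ) from exc
    z = interp(grid.nodes()).reshape(grid.shape)
    field = HeightField(grid, z)
    if not field.valid.any():
        raise GeometryError("no grid node lies inside the point-cloud hull")
    return field


# ---------------------------------------------------------------------------
# step 2: LOESS
# ---------------------------------------------------------------------------

def _design(dx, dy, degree):
    cols = [np.ones_like(dx), dx, dy]
    if degree == 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.column_stack(cols)


def _loess_at_nodes(xy, z, nodes, cfg, robust_w=None):
    n = len(xy)
    n_coef = 6 if cfg.degree == 2 else 3
    k = max(int(np.ceil(cfg.span_fraction * n)), n_coef)
    k = min(k, n)
    if k < n_coef:
        raise ParameterError(
            f"need >= {n_coef} points for a degree-{cfg.degree} local fit, "
            f"have {n}")
    tree = cKDTree(xy)
    dist, idx = tree.query(nodes, k=k, workers=-1)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.full(len(nodes), np.nan)
    for i, node in enumerate(nodes):
        d, j = dist[i], idx[i]
        dmax = d[-1]
        if dmax <= 0:
            w = np.ones(k)
        else:
            w = (1 - np.clip(d / dmax, 0, 1) ** 3) ** 3
        if robust_w is not None:
            w = w * robust_w[j]
        # keep at least the closest points weighted even when dmax repeats
        if np.count_nonzero(w) < n_coef:
            w = np.maximum(w, 1e-12)
        scale = dmax if dmax > 0 else 1.0
        dx = (xy[j, 0] - node[0]) / scale
        dy = (xy[j, 1] - node[1]) / scale
        for degree in (cfg.degree, 1) if cfg.degree == 2 else (1,):
            A = _design(dx, dy, degree)
            Aw = A * w[:, None]
            ata = A.T @ Aw
            if np.linalg.cond(ata) > CONDITION_LIMIT:
                continue
            coef = np.linalg.solve(ata, Aw.T @ z[j])
            out[i] = coef[0]
            break
        else:
            logger.debug("rank-deficient local fit at node %s", node)
    return out


def loess_smooth(field_or_points, cfg: LoessConfig = None,
                 grid: GridSpec = None) -> HeightField:
    """Tricube-weighted local polynomial regression evaluated at grid nodes.

    At each node the nearest ``ceil(span_fraction * N)`` samples are fit with
    a bivariate polynomial of the configured degree, weighted by
    ``w = (1 - (d / d_max)^3)^3``, and the fit is evaluated at the node.
    Accepts either a :class:`HeightField` (its valid nodes become the
    samples) or a :class:`LeafletPointCloud` plus an explicit grid.
    """
    cfg = cfg or LoessConfig()
    if isinstance(field_or_points, HeightField):
        samples = field_or_points.sample_points()
        grid = grid or field_or_points.grid
        restrict = field_or_points.valid.ravel()
    else:
        if grid is None:
            raise ParameterError("a grid is required when smoothing a cloud")
        samples = field_or_points.coords
        restrict = None
    xy, z = samples[:, :2], samples[:, 2]
    nodes = grid.nodes()
    zhat = _loess_at_nodes(xy, z, nodes, cfg)
    for _ in range(cfg.robustness_iters):
        # bisquare robustness weights from residuals at the sample locations
        fit_at_samples = _loess_at_nodes(xy, z, xy, cfg)
        resid = z - fit_at_samples
        s = np.nanmedian(np.abs(resid))
        rw = np.clip(1 - (resid / (6 * s + 1e-300)) ** 2, 0, None) ** 2
        rw[~np.isfinite(rw)] = 0
        zhat = _loess_at_nodes(xy, z, nodes, cfg, robust_w=rw)
    if restrict is not None:
        zhat = np.where(restrict, zhat, np.nan)
    return HeightField(grid, zhat.reshape(grid.shape))


def fit_leaflet(points: LeafletPointCloud, grid: GridSpec,
                cfg: LoessConfig = None) -> HeightField:
    """The canonical surface operation: scattered interpolation onto the
    grid, then LOESS smoothing of the gridded samples."""
    gridded = interpolate_scattered(points, grid)
    return loess_smooth(gridded, cfg or LoessConfig())


# ---------------------------------------------------------------------------
# trajectory-derived height fields
# ---------------------------------------------------------------------------

def phosphate_height_field(traj: LipidTrajectory, leaflet: str,
                           grid: GridSpec, head_name: str = "P") -> HeightField:
    """Time-and-lipid average head-particle height per lateral grid cell.

    Leaflet membership ("upper"/"lower") is decided per frame by the sign of
    the head z relative to the mean head height (the midplane estimate).
    Cells that never receive a sample are invalid.
    """
    if leaflet not in ("upper", "lower"):
        raise ParameterError("leaflet must be 'upper' or 'lower'")
    heads = traj.head_indices(head_name)
    if len(heads) == 0:
        raise SelectionError(f"no head particles named {head_name!r}")
    nx, ny = grid.shape
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny), dtype=int)
    for f in range(traj.n_frames):
        pos = traj.coords[f, heads]
        midplane = pos[:, 2].mean()
        sel = pos[:, 2] >= midplane if leaflet == "upper" else pos[:, 2] < midplane
        p = pos[sel]
        ix = np.round((p[:, 0] - grid.x_range[0]) / grid.spacing).astype(int)
        iy = np.round((p[:, 1] - grid.y_range[0]) / grid.spacing).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(total, (ix[ok], iy[ok]), p[ok, 2])
        np.add.at(count, (ix[ok], iy[ok]), 1)
    with np.errstate(invalid="ignore"):
        z = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    if not np.any(count > 0):
        raise SelectionError("no head particle fell inside the grid")
    return HeightField(grid, z)
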