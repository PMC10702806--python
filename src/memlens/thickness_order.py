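"""Thickness maps and profiles, two-Gaussian mixture fits, and deuterium
order parameters.

Local membrane thickness is the difference between the two leaflet height
fields. Thickness (and order) distributions are summarized with a 1-D
Gaussian mixture fitted by expectation-maximization, which separates an
unperturbed population from a locally thinned/disordered one. Acyl-chain
order is quantified by the deuterium order parameter

    S_CD = < (3 cos^2 theta - 1) / 2 >

where theta is the angle between a C-H bond and the membrane normal (+z),
averaged over lipids, frames and hydrogens, per chain carbon.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (AnnotationError, EmptyCloudError, ParameterError,
                     SelectionError)
from .diffgeo import ScalarMap
from .io import LeafletPointCloud, LipidTrajectory
from .surfaces import GridSpec, HeightField

logger = logging.getLogger(__name__)


@dataclass
class AxisProfile:
    """Mean height vs position along a lateral axis, in contiguous bins."""

    origin: np.ndarray
    direction: np.ndarray      # unit lateral vector
    bin_width: float
    bin_centers: np.ndarray
    mean_z: np.ndarray
    counts: np.ndarray


@dataclass
class GaussianMixtureResult:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool


@dataclass
class OrderProfile:
    """Per-carbon S_CD with the chain average reported as a magnitude and
    the sign kept alongside."""

    carbons: np.ndarray
    s_cd: np.ndarray             # signed, per carbon
    sem: np.ndarray              # per carbon, over lipids
    chain_average: float         # |mean over carbons|
    chain_average_signed: float
    chain_sem: float


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def thickness_map(upper: HeightField, lower: HeightField) -> ScalarMap:
    """Local thickness = z_upper - z_lower on the upper field's grid."""
    if lower.grid != upper.grid:
        lower = lower.resample(upper.grid)
    values = upper.z - lower.z
    valid = upper.valid & lower.valid
    if not valid.any():
        raise EmptyCloudError("leaflet fields have no common valid region")
    return ScalarMap(upper.grid, np.where(valid, values, np.nan), units="A")


def axis_profile(data, origin, direction, bin_width: float) -> AxisProfile:
    """Project samples onto a lateral axis, bin, and average the height."""
    direction = np.asarray(direction, dtype=float)[:2]
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ParameterError("axis direction has zero length")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    u = direction / norm
    origin = np.asarray(origin, dtype=float)[:2]
    if isinstance(data, HeightField):
        samples = data.sample_points()
    elif isinstance(data, LeafletPointCloud):
        samples = data.coords
    else:
        samples = np.asarray(data, dtype=float).reshape(-1, 3)
    if len(samples) == 0:
        raise EmptyCloudError("no samples to profile")
    t = (samples[:, :2] - origin) @ u
    lo = np.floor(t.min() / bin_width) * bin_width
    n_bins = int(np.ceil((t.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=samples[:, 2], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return AxisProfile(origin, u, bin_width, centers, mean_z, counts)


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture by EM
# ---------------------------------------------------------------------------

def _kmeanspp_centers(x, k, rng):
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(len(x))])
        else:
            centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.asarray(centers, dtype=float)


def fit_gaussian_mixture(samples, k: int = 2, seed: int = 0,
                         tol: float = 1e-8,
                         max_iter: int = 500) -> GaussianMixtureResult:
    """Fit a k-component 1-D Gaussian mixture by EM (k-means++ init).

    The log-likelihood is checked to be non-decreasing at every iteration;
    a component whose sd collapses below 1e-6 of the data sd is pruned with
    a warning. Components are returned sorted by decreasing mean.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < 10 * k:
        raise ParameterError(f"need >= {10 * k} samples for k={k}")
    rng = np.random.default_rng(seed)
    data_sd = max(x.std(), 1e-300)
    means = _kmeanspp_centers(x, k, rng)
    sds = np.full(k, data_sd)
    weights = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    while n_iter < max_iter:
        n_iter += 1
        # E-step (log domain)
        logp = (np.log(weights)[None, :]
                - 0.5 * np.log(2 * np.pi * sds[None, :] ** 2)
                - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2)
        lse = np.logaddexp.reduce(logp, axis=1)
        ll = float(lse.sum())
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = ((resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
               / np.maximum(nk, 1e-300))
        sds = np.sqrt(np.maximum(var, 0))
        collapsed = sds < 1e-6 * data_sd
        if collapsed.any() and len(means) > 1:
            logger.warning("pruning %d collapsed mixture component(s)",
                           int(collapsed.sum()))
            keep = ~collapsed
            means, sds = means[keep], sds[keep]
            weights = weights[keep] / weights[keep].sum()
            ll_prev = -np.inf
            continue
        sds = np.maximum(sds, 1e-6 * data_sd)
        if np.isfinite(ll_prev) and ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    order = np.argsort(means)[::-1]
    return GaussianMixtureResult(len(means), weights[order], means[order],
                                 sds[order], ll_prev, n_iter, converged)


def select_k_by_bic(samples, k_candidates=(1, 2), seed: int = 0):
    """Pick the mixture size with the lowest BIC; returns (k, fits dict)."""
    x = np.asarray(samples, dtype=float).ravel()
    fits = {k: fit_gaussian_mixture(x, k=k, seed=seed) for k in k_candidates}
    bic = {k: (3 * k - 1) * np.log(len(x)) - 2 * f.log_likelihood
           for k, f in fits.items()}
    best = min(bic, key=bic.get)
    return best, fits


# ---------------------------------------------------------------------------
# deuterium order parameters
# ---------------------------------------------------------------------------

def _ch_vectors(traj: LipidTrajectory, carbon: int):
    """(F, nH, 3) C->H bond vectors for one chain carbon, plus H lipid ids."""
    c_idx = np.flatnonzero(traj.names == f"C{carbon}")
    pat = re.compile(rf"^H{carbon}[A-Z0-9]*$")
    h_idx = np.array([i for i, n in enumerate(traj.names) if pat.match(n)],
                     dtype=int)
    if len(c_idx) == 0 or len(h_idx) == 0:
        raise AnnotationError(
            f"carbon C{carbon} or its hydrogens missing from the trajectory")
    c_by_lipid = {int(r): int(i) for r, i in zip(traj.res_id[c_idx], c_idx)}
    try:
        partner = np.array([c_by_lipid[int(r)] for r in traj.res_id[h_idx]])
    except KeyError as exc:
        raise AnnotationError(
            f"hydrogen of C{carbon} without a carbon in the same lipid"
        ) from exc
    v = traj.coords[:, h_idx, :] - traj.coords[:, partner, :]
    return v, traj.res_id[h_idx]


def _p2_of(v):
    cos = v[..., 2] / np.linalg.norm(v, axis=-1)
    return 0.5 * (3 * cos ** 2 - 1)


def order_parameters(traj: LipidTrajectory,
                     carbons=tuple(range(2, 16))) -> OrderProfile:
    """Per-carbon deuterium order parameters and their chain average.

    S_CD for carbon k averages P2(cos theta) of every C(k)-H bond over all
    lipids, frames and hydrogens; the standard error is computed over
    per-lipid averages. The chain average (carbons 2-15 by default) is
    reported as a magnitude, with the signed value retained.
    """
    carbons = np.asarray(list(carbons), dtype=int)
    s_cd, sems, lipid_means = [], [], []
    for k in carbons:
        v, lip = _ch_vectors(traj, int(k))
        p2 = _p2_of(v)                     # (F, nH)
        s_cd.append(float(p2.mean()))
        # per-lipid averages -> SEM across lipids
        uniq, inv = np.unique(lip, return_inverse=True)
        per_lipid = np.zeros(len(uniq))
        np.add.at(per_lipid, inv, p2.mean(axis=0))
        per_lipid /= np.bincount(inv)
        lipid_means.append(per_lipid)
        sems.append(float(per_lipid.std(ddof=1) / np.sqrt(len(uniq)))
                    if len(uniq) > 1 else 0.0)
    s_cd = np.asarray(s_cd)
    chain_per_lipid = np.mean(lipid_means, axis=0)
    signed = float(s_cd.mean())
    chain_sem = (float(chain_per_lipid.std(ddof=1)
                       / np.sqrt(len(chain_per_lipid)))
                 if len(chain_per_lipid) > 1 else 0.0)
    return OrderProfile(carbons, s_cd, np.asarray(sems),
                        abs(signed), signed, chain_sem)


def local_order_map(traj: LipidTrajectory, grid: GridSpec,
                    carbons=tuple(range(2, 16)), leaflet: str = None,
                    head_name: str = "P") -> ScalarMap:
    """Average chain S_CD per lateral grid cell of the lipid head position.

    ``leaflet`` restricts to "upper"/"lower" lipids (by head z relative to
    the per-frame mean head height); cells without samples are invalid.
    """
    heads = traj.head_indices(head_name)
    if len(heads) == 0:
        raise SelectionError(f"no head particles named {head_name!r}")
    head_lipid = traj.res_id[heads]
    # per-lipid per-frame chain-average P2
    sums = None
    count = 0
    for k in carbons:
        v, lip = _ch_vectors(traj, int(k))
        p2 = _p2_of(v)
        uniq, inv = np.unique(lip, return_inverse=True)
        acc = np.zeros((traj.n_frames, len(uniq)))
        np.add.at(acc.T, inv, p2.T)
        acc /= np.bincount(inv)[None, :]
        if sums is None:
            sums, lipid_ids = acc, uniq
        else:
            sums += acc
        count += 1
    chain = sums / count                              # (F, n_lipids)
    order_by_lipid = {int(l): j for j, l in enumerate(lipid_ids)}
    col = np.array([order_by_lipid[int(l)] for l in head_lipid])
    nx, ny = grid.shape
    total = np.zeros((nx, ny))
    n = np.zeros((nx, ny), dtype=int)
    for f in range(traj.n_frames):
        pos = traj.coords[f, heads]
        if leaflet is not None:
            mid = pos[:, 2].mean()
            sel = pos[:, 2] >= mid if leaflet == "upper" else pos[:, 2] < mid
        else:
            sel = np.ones(len(heads), dtype=bool)
        p = pos[sel]
        vals = chain[f, col[sel]]
        ix = np.round((p[:, 0] - grid.x_range[0]) / grid.spacing).astype(int)
        iy = np.round((p[:, 1] - grid.y_range[0]) / grid.spacing).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(total, (ix[ok], iy[ok]), vals[ok])
        np.add.at(n, (ix[ok], iy[ok]), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return ScalarMap(grid, values, units="dimensionless")
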