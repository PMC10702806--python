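"""Solvent-accessible surface area (Shrake-Rupley) and buried interface
area between subunit groups.

Each atom's accessible surface is the sphere of radius r_vdw + r_probe;
quasi-uniform test points on that sphere are checked for occlusion by
neighboring expanded spheres, and the accessible area is the unoccluded
fraction times the sphere area. The buried interface between two groups is

    buried = SASA(A alone) + SASA(B alone) - SASA(A u B)

reported both as the total and halved (the per-side convention).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnnotationError, ParameterError, SelectionError
from .io import AtomModel


@dataclass
class SasaConfig:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    ignore_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ParameterError("probe_radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ParameterError("need >= 32 sphere points")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    cos_t = 1 - 2 * i / n
    sin_t = np.sqrt(1 - cos_t ** 2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sasa(model: AtomModel, cfg: SasaConfig = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2)."""
    cfg = cfg or SasaConfig()
    if cfg.ignore_hydrogens:
        keep = np.array([e.strip().upper() != "H" for e in model.element])
        if not keep.all():
            out = np.zeros(len(model))
            out[keep] = sasa(model.subset(np.flatnonzero(keep)),
                             SasaConfig(cfg.probe_radius,
                                        cfg.n_sphere_points,
                                        ignore_hydrogens=False))
            return out
    radii = model.vdw_radius
    if np.any(~np.isfinite(radii)):
        raise AnnotationError("every atom needs a finite vdW radius")
    coords = model.coords
    n = len(coords)
    expanded = radii + cfg.probe_radius
    unit = fibonacci_sphere(cfg.n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        accessible = np.ones(cfg.n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = (accessible.mean() * 4 * np.pi * expanded[i] ** 2)
    return areas


def interface_area(model: AtomModel, group_a, group_b,
                   cfg: SasaConfig = None) -> dict:
    """Buried SASA between two disjoint atom groups.

    ``group_a``/``group_b`` are boolean masks or index arrays into the
    model. Returns ``{"buried_total": ..., "buried_half": ...,
    "sasa_a": ..., "sasa_b": ..., "sasa_ab": ...}`` in Angstrom^2.
    """
    cfg = cfg or SasaConfig()
    ia = _as_indices(group_a, len(model))
    ib = _as_indices(group_b, len(model))
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise SelectionError("groups overlap")
    a = model.subset(ia)
    b = model.subset(ib)
    ab = model.subset(np.concatenate([ia, ib]))
    sasa_a = float(sasa(a, cfg).sum())
    sasa_b = float(sasa(b, cfg).sum())
    sasa_ab = float(sasa(ab, cfg).sum())
    buried = sasa_a + sasa_b - sasa_ab
    return {"buried_total": buried, "buried_half": buried / 2.0,
            "sasa_a": sasa_a, "sasa_b": sasa_b, "sasa_ab": sasa_ab}


def _as_indices(group, n) -> np.ndarray:
    g = np.asarray(group)
    if g.dtype == bool:
        if len(g) != n:
            raise SelectionError("boolean group mask has wrong length")
        return np.flatnonzero(g)
    return g.astype(int)
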