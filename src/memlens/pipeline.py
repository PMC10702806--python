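"""Reproducible end-to-end runs.

Two entry points mirror the two data sources:

* ``run_cryoet_pipeline`` — two leaflet point sets (CSV tables or MRC masks
  with a threshold) -> smooth leaflet fields -> curvature and thickness maps
  -> regional radii of curvature and mean thickness near/far from a stated
  lateral center.
* ``run_md_pipeline`` — an annotated lipid trajectory -> leaflet height
  fields, pooled per-frame thickness samples with a two-Gaussian fit, order
  profiles and maps, flip-flop events, and optional gate-distance / RMSD
  series.

Both are deterministic given their config, and every report records a hash
of the resolved configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffgeo, dynamics, io, surfaces, thickness_order
from .errors import ConfigError

logger = logging.getLogger(__name__)


def _check_keys(data: dict, cls) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    return data


@dataclass
class CryoETConfig:
    """Configuration of the map-derived membrane analysis."""

    upper: str = None              # CSV point table or MRC mask
    lower: str = None
    threshold: float = None        # required for MRC masks
    spacing: float = 4.0
    span_fraction: float = 0.20
    degree: int = 2
    center: tuple = None           # lateral (x, y) of the protein axis; required
    region_radius: float = 40.0    # "protein vicinity" disk radius
    grid_margin: float = 0.0
    outdir: str = "memlens_out"

    @classmethod
    def from_dict(cls, data: dict) -> "CryoETConfig":
        return cls(**_check_keys(dict(data), cls))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.upper is None or self.lower is None:
            raise ConfigError("both 'upper' and 'lower' leaflet inputs are "
                              "required")
        for p in (self.upper, self.lower):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.center is None:
            raise ConfigError("'center' (lateral x, y of the region of "
                              "interest) is required")


@dataclass
class MDConfig:
    """Configuration of the trajectory-derived membrane analysis."""

    trajectory: str = None
    topology: str = None
    spacing: float = 4.0
    carbons: tuple = tuple(range(2, 16))
    hysteresis_gap: float = 10.0
    mixture_k: int = 2
    seed: int = 0
    head_name: str = "P"
    gate: dict = None              # tm2_chain/tm2_residues/tm7_chain/...
    reference: str = None          # PDB for RMSD; defaults to frame 0
    rmsd_atom_names: tuple = ("CA",)
    outdir: str = "memlens_out"

    @classmethod
    def from_dict(cls, data: dict) -> "MDConfig":
        return cls(**_check_keys(dict(data), cls))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.trajectory is None:
            raise ConfigError("'trajectory' input is required")
        if not Path(self.trajectory).exists():
            raise ConfigError(f"input path does not exist: {self.trajectory}")


def load_config(path, kind: str):
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cls = CryoETConfig if kind == "cryoet" else MDConfig
    return cls.from_dict(data)


def config_hash(cfg) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cryo-ET-style pipeline
# ---------------------------------------------------------------------------

def _load_cloud(path, threshold, label):
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".map"):
        if threshold is None:
            raise ConfigError("a 'threshold' is required for MRC mask input")
        return io.mask_to_points(io.read_volume(path), threshold,
                                 leaflet_label=label)
    return io.read_points_csv(path, leaflet_label=label)


def _write_map_csv(path, grid, values):
    pd.DataFrame(values, index=grid.x, columns=grid.y).to_csv(path)


def run_cryoet_pipeline(cfg: CryoETConfig, write: bool = True) -> dict:
    """Masks/point tables -> surfaces -> curvature & thickness summary."""
    cfg.validate()
    t0 = time.perf_counter()
    upper_pts = _load_cloud(cfg.upper, cfg.threshold, "upper")
    lower_pts = _load_cloud(cfg.lower, cfg.threshold, "lower")
    xy = np.vstack([upper_pts.xy, lower_pts.xy])
    grid = surfaces.GridSpec.from_points(xy, spacing=cfg.spacing,
                                         margin=cfg.grid_margin)
    loess = surfaces.LoessConfig(span_fraction=cfg.span_fraction,
                                 degree=cfg.degree)
    logger.info("fitting leaflet surfaces (grid %s)", grid.shape)
    upper = surfaces.fit_leaflet(upper_pts, grid, loess)
    lower = surfaces.fit_leaflet(lower_pts, grid, loess)
    h_upper = diffgeo.mean_curvature_map(upper)
    h_lower = diffgeo.mean_curvature_map(lower)
    thick = thickness_order.thickness_map(upper, lower)
    center, rad = cfg.center, cfg.region_radius
    near = diffgeo.region_mask(grid, center, rad)
    far = ~near
    summary = {"config_hash": config_hash(cfg), "grid_shape": grid.shape,
               "n_points": {"upper": len(upper_pts), "lower": len(lower_pts)}}
    for name, cmap in (("upper", h_upper), ("lower", h_lower)):
        r_near, h_near = diffgeo.radius_of_curvature(cmap, region=near)
        r_far, h_far = diffgeo.radius_of_curvature(cmap, region=far)
        summary[f"{name}_leaflet"] = {
            "radius_near_A": r_near, "mean_H_near_invA": h_near,
            "radius_far_A": r_far, "mean_H_far_invA": h_far}
    summary["thickness_A"] = {
        "near_mean": float(np.nanmean(thick.values[near & thick.valid])),
        "far_mean": float(np.nanmean(thick.values[far & thick.valid])),
        "center_value": _value_at(thick, center)}
    logger.info("cryo-ET pipeline finished in %.2f s",
                time.perf_counter() - t0)
    if write:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_map_csv(out / "upper_height.csv", grid, upper.z)
        _write_map_csv(out / "lower_height.csv", grid, lower.z)
        _write_map_csv(out / "upper_mean_curvature.csv", grid, h_upper.values)
        _write_map_csv(out / "lower_mean_curvature.csv", grid, h_lower.values)
        _write_map_csv(out / "thickness.csv", grid, thick.values)
        _write_summary(out / "summary.json", summary)
    return summary


def _value_at(smap, center):
    ix = int(round((center[0] - smap.grid.x_range[0]) / smap.grid.spacing))
    iy = int(round((center[1] - smap.grid.y_range[0]) / smap.grid.spacing))
    nx, ny = smap.grid.shape
    if 0 <= ix < nx and 0 <= iy < ny and smap.valid[ix, iy]:
        return float(smap.values[ix, iy])
    return None


def _write_summary(path, summary):
    # deterministic serialization: sorted keys, no timestamps in content
    body = json.dumps(summary, sort_keys=True, indent=2, default=str)
    Path(path).write_text(body + "\n")


# ---------------------------------------------------------------------------
# MD-style pipeline
# ---------------------------------------------------------------------------

def thickness_samples(traj, grid, head_name: str = "P") -> np.ndarray:
    """Pooled per-frame local thickness samples.

    For every frame, heads are split into leaflets about the mean head
    height and averaged per lateral cell; cells where both leaflets have
    samples contribute one thickness value (upper - lower) to the pool.
    """
    heads = traj.head_indices(head_name)
    nx, ny = grid.shape
    samples = []
    for f in range(traj.n_frames):
        pos = traj.coords[f, heads]
        mid = pos[:, 2].mean()
        maps = []
        for sel in (pos[:, 2] >= mid, pos[:, 2] < mid):
            p = pos[sel]
            total = np.zeros((nx, ny))
            count = np.zeros((nx, ny), dtype=int)
            ix = np.round((p[:, 0] - grid.x_range[0]) / grid.spacing).astype(int)
            iy = np.round((p[:, 1] - grid.y_range[0]) / grid.spacing).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            np.add.at(total, (ix[ok], iy[ok]), p[ok, 2])
            np.add.at(count, (ix[ok], iy[ok]), 1)
            maps.append((total, count))
        both = (maps[0][1] > 0) & (maps[1][1] > 0)
        if both.any():
            up = maps[0][0][both] / maps[0][1][both]
            lo = maps[1][0][both] / maps[1][1][both]
            samples.append(up - lo)
    if not samples:
        return np.empty(0)
    return np.concatenate(samples)


def run_md_pipeline(cfg: MDConfig, traj=None, write: bool = True) -> dict:
    """Trajectory -> height/order/thickness/event summary.

    ``traj`` may be given directly (e.g. from the synthetic generator) to
    bypass file reading; otherwise ``cfg.trajectory`` is loaded.
    """
    t0 = time.perf_counter()
    if traj is None:
        cfg.validate()
        traj = io.read_trajectory(cfg.trajectory, topology=cfg.topology)
    if traj.n_frames == 0:
        raise ConfigError("trajectory has no frames")
    heads = traj.head_indices(cfg.head_name)
    xy = traj.coords[:, heads, :2].reshape(-1, 2)
    grid = surfaces.GridSpec.from_points(xy, spacing=cfg.spacing)
    summary = {"config_hash": config_hash(cfg),
               "n_frames": traj.n_frames, "n_lipids": len(heads)}
    upper = surfaces.phosphate_height_field(traj, "upper", grid,
                                            cfg.head_name)
    lower = surfaces.phosphate_height_field(traj, "lower", grid,
                                            cfg.head_name)
    samples = thickness_samples(traj, grid, cfg.head_name)
    summary["thickness_A"] = {"mean": float(samples.mean()),
                              "sd": float(samples.std())}
    if len(samples) >= 10 * cfg.mixture_k:
        fit = thickness_order.fit_gaussian_mixture(
            samples, k=cfg.mixture_k, seed=cfg.seed)
        summary["thickness_mixture"] = {
            "means_A": fit.means.tolist(), "sds_A": fit.sds.tolist(),
            "weights": fit.weights.tolist(), "converged": fit.converged}
    profile = thickness_order.order_parameters(traj, cfg.carbons)
    summary["order"] = {
        "chain_average": profile.chain_average,
        "chain_average_signed": profile.chain_average_signed,
        "per_carbon": dict(zip(map(int, profile.carbons),
                               map(float, profile.s_cd)))}
    log = dynamics.detect_flipflops(traj, cfg.hysteresis_gap, cfg.head_name)
    summary["flipflops"] = {"count": len(log)}
    if cfg.gate:
        sel = dynamics.GateSelection(**cfg.gate)
        series = dynamics.gate_distance(traj, sel)
        summary["gate_distance_A"] = {"mean": float(series.mean()),
                                      "min": float(series.min()),
                                      "max": float(series.max())}
    ref = (io.read_structure(cfg.reference).coords if cfg.reference
           else traj.coords[0])
    rmsd = dynamics.superpose_rmsd(traj, ref)
    summary["rmsd_A"] = {"mean": float(rmsd.mean()),
                         "final": float(rmsd[-1])}
    logger.info("MD pipeline finished in %.2f s", time.perf_counter() - t0)
    if write:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_map_csv(out / "upper_height.csv", grid, upper.z)
        _write_map_csv(out / "lower_height.csv", grid, lower.z)
        pd.DataFrame({"carbon": profile.carbons,
                      "s_cd": profile.s_cd,
                      "sem": profile.sem}).to_csv(
            out / "order_profile.csv", index=False)
        log.to_frame().to_csv(out / "flipflops.csv", index=False)
        np.savetxt(out / "rmsd.csv", rmsd, header="rmsd_A", comments="")
        _write_summary(out / "summary.json", summary)
    return summary
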