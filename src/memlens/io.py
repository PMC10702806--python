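"""Readers, writers, and core containers for the formats the pipeline touches.

Containers
----------
``VolumeGrid``        3-D scalar volume with physical voxel geometry (MRC2014).
``LeafletPointCloud`` labeled 3-D points sampled on one membrane leaflet.
``AtomModel``         flat per-atom arrays for a static structure (PDB/mmCIF).
``LipidTrajectory``   time-ordered coordinate frames with per-atom annotations.

Conventions: all coordinates are in Angstrom; voxel indices are 0-based and
refer to voxel centers, so the physical position of voxel (i, j, k) is
``origin + (i, j, k) * voxel_size``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, EmptyCloudError, FormatError, GeometryError

logger = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (Angstrom), the standard table for SASA.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "FE": 1.94,
}
DEFAULT_VDW_RADIUS = 1.70


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """A 3-D scalar field on a regular grid, axis order (x, y, z)."""

    values: np.ndarray            # shape (nx, ny, nz)
    voxel_size: np.ndarray        # (3,) Angstrom per axis
    origin: np.ndarray            # (3,) Angstrom, position of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise FormatError("volume values must be a 3-D array")
        if np.any(self.voxel_size <= 0):
            raise FormatError(f"voxel_size must be positive, got {self.voxel_size}")

    def voxel_center(self, ijk) -> np.ndarray:
        """Physical coordinate (Angstrom) of voxel-center (i, j, k)."""
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size


@dataclass
class LeafletPointCloud:
    """Scattered 3-D points (Angstrom) sampled on one membrane leaflet."""

    coords: np.ndarray            # (N, 3)
    leaflet_label: str = "upper"  # "upper"/"cytosolic" or "lower"/"lumenal"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError("coords must be an (N, 3) array")
        if len(self.coords) < 3:
            raise EmptyCloudError(
                f"point cloud needs >= 3 points, got {len(self.coords)}")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def xy(self) -> np.ndarray:
        return self.coords[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]


@dataclass
class AtomModel:
    """Flat per-atom arrays for a static structural model."""

    element: np.ndarray           # (N,) str
    name: np.ndarray              # (N,) str, atom name e.g. "CA"
    res_id: np.ndarray            # (N,) int
    res_name: np.ndarray          # (N,) str
    chain_id: np.ndarray          # (N,) str
    coords: np.ndarray            # (N, 3) Angstrom
    vdw_radius: np.ndarray = None  # (N,) Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for attr in ("element", "name", "res_name", "chain_id"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype="U6"))
        self.res_id = np.asarray(self.res_id, dtype=int)
        if self.vdw_radius is None:
            self.vdw_radius = assign_vdw_radii(self.element)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        lengths = {len(self.element), len(self.name), len(self.res_id),
                   len(self.res_name), len(self.chain_id), n,
                   len(self.vdw_radius)}
        if len(lengths) != 1:
            raise FormatError("per-atom arrays have inconsistent lengths")
        if np.any(self.vdw_radius <= 0):
            raise AnnotationError("all vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices) -> "AtomModel":
        idx = np.asarray(indices)
        return AtomModel(self.element[idx], self.name[idx], self.res_id[idx],
                         self.res_name[idx], self.chain_id[idx],
                         self.coords[idx], self.vdw_radius[idx])

    def select(self, chain_id=None, res_ids=None, atom_names=None) -> np.ndarray:
        """Boolean mask over atoms matching all given criteria."""
        mask = np.ones(len(self), dtype=bool)
        if chain_id is not None:
            mask &= self.chain_id == chain_id
        if res_ids is not None:
            mask &= np.isin(self.res_id, np.asarray(list(res_ids)))
        if atom_names is not None:
            mask &= np.isin(self.name, np.asarray(list(atom_names)))
        return mask


@dataclass
class LipidTrajectory:
    """Time-ordered coordinate frames with constant per-atom annotations.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom. Heads, chain
    carbons and their hydrogens are identified by atom name convention:
    the head reference particle is named ``P``, chain carbon *k* is ``C<k>``
    and its hydrogens are named ``H<k>A``, ``H<k>B``...
    """

    coords: np.ndarray                       # (F, N, 3)
    names: np.ndarray                        # (N,) atom names
    res_id: np.ndarray                       # (N,) lipid/molecule id
    res_name: np.ndarray                     # (N,)
    times: np.ndarray = None                 # (F,) strictly increasing
    box: np.ndarray = None                   # (F, 3) Angstrom
    chain_id: np.ndarray = None              # (N,), optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("trajectory coords must have shape (F, N, 3)")
        n_frames, n_atoms = self.coords.shape[:2]
        self.names = np.asarray(self.names, dtype="U6")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U6")
        if self.chain_id is None:
            self.chain_id = np.full(n_atoms, "A", dtype="U6")
        if not (len(self.names) == len(self.res_id) == len(self.res_name)
                == n_atoms):
            raise FormatError("annotation arrays do not match atom count")
        if self.times is None:
            self.times = np.arange(n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != n_frames:
            raise FormatError("times length does not match frame count")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(n_frames, 3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(self, names=None, res_name=None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            mask &= np.isin(self.names, np.asarray(list(names)))
        if res_name is not None:
            mask &= self.res_name == res_name
        return mask

    def head_indices(self, head_name: str = "P") -> np.ndarray:
        """Indices of the head reference particle of every lipid."""
        idx = np.flatnonzero(self.names == head_name)
        return idx

    def frame_model(self, i: int) -> AtomModel:
        """A single frame as an :class:`AtomModel` (element from name[0])."""
        elements = np.array([n[0] for n in self.names], dtype="U6")
        return AtomModel(elements, self.names, self.res_id, self.res_name,
                         self.chain_id, self.coords[i])


# ---------------------------------------------------------------------------
# radii
# ---------------------------------------------------------------------------

def assign_vdw_radii(elements, table=None, default=DEFAULT_VDW_RADIUS) -> np.ndarray:
    """Map element symbols to vdW radii; unknown elements get ``default``."""
    table = VDW_RADII if table is None else table
    elements = np.asarray(elements)
    radii = np.empty(len(elements), dtype=float)
    unknown = set()
    for i, el in enumerate(elements):
        key = str(el).strip().upper()
        if key in table:
            radii[i] = table[key]
        else:
            radii[i] = default
            unknown.add(key)
    if unknown:
        logger.warning("unknown elements %s assigned default radius %.2f A",
                       sorted(unknown), default)
    return radii


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeGrid:
    """Read an MRC2014 volume into a :class:`VolumeGrid` (axis order x,y,z)."""
    import mrcfile

    try:
        with mrcfile.open(str(path), permissive=False) as mrc:
            data = np.asarray(mrc.data)
            vs = mrc.voxel_size
            voxel = np.array([vs.x, vs.y, vs.z], dtype=float)
            org = mrc.header.origin
            origin = np.array([org.x, org.y, org.z], dtype=float)
    except ValueError as exc:
        raise FormatError(f"malformed MRC file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    # mrcfile stores data as (z, y, x); transpose to our (x, y, z) convention
    return VolumeGrid(np.ascontiguousarray(data.transpose(2, 1, 0)),
                      voxel, origin)


def write_volume(path, vol: VolumeGrid) -> None:
    """Write a :class:`VolumeGrid` as an MRC2014 file."""
    import mrcfile

    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(np.ascontiguousarray(
            vol.values.transpose(2, 1, 0)).astype(np.float32))
        mrc.voxel_size = tuple(vol.voxel_size)
        mrc.header.origin = tuple(vol.origin)


def mask_to_points(vol: VolumeGrid, threshold: float,
                   leaflet_label: str = "upper") -> LeafletPointCloud:
    """One point per super-threshold voxel, at the voxel-center coordinate."""
    if not np.isfinite(threshold):
        raise FormatError("threshold must be finite")
    idx = np.argwhere(vol.values > threshold)
    if len(idx) == 0:
        raise EmptyCloudError(
            f"no voxels above threshold {threshold} "
            f"(max value {vol.values.max():g})")
    coords = vol.origin + idx * vol.voxel_size
    return LeafletPointCloud(coords, leaflet_label=leaflet_label,
                             provenance=f"mask threshold {threshold}")


def split_leaflets(cloud: LeafletPointCloud):
    """Fallback splitter for a single whole-membrane cloud.

    PCA-aligns the patch so its smallest-variance axis is the membrane
    normal, then splits by the sign of the coordinate along that axis.
    Returns (upper, lower) clouds in the original coordinate frame.
    """
    coords = cloud.coords
    center = coords.mean(axis=0)
    centered = coords - center
    # smallest singular direction = membrane normal for a flat-ish patch
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    proj = centered @ normal
    up, down = proj >= 0, proj < 0
    if up.sum() < 3 or down.sum() < 3:
        raise GeometryError("leaflet split produced a degenerate side")
    return (LeafletPointCloud(coords[up], "upper", cloud.provenance),
            LeafletPointCloud(coords[down], "lower", cloud.provenance))


# ---------------------------------------------------------------------------
# point tables
# ---------------------------------------------------------------------------

def write_points_csv(path, cloud: LeafletPointCloud) -> None:
    df = pd.DataFrame(cloud.coords, columns=["x", "y", "z"])
    df.to_csv(path, index=False)


def read_points_csv(path, leaflet_label: str = "upper") -> LeafletPointCloud:
    """Read an x,y,z table (CSV with header, or whitespace-separated)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse point table {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if {"x", "y", "z"}.issubset(cols):
        df.columns = cols
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    elif df.shape[1] >= 3:
        # headerless table: first row was consumed as header, recover it
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#")
        coords = df.iloc[:, :3].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: need at least 3 coordinate columns")
    return LeafletPointCloud(coords, leaflet_label=leaflet_label,
                             provenance=str(path))


# ---------------------------------------------------------------------------
# structures (PDB / mmCIF via biotite)
# ---------------------------------------------------------------------------

def read_structure(path, default_radius: float = DEFAULT_VDW_RADIUS) -> AtomModel:
    """Read a PDB or mmCIF structure into an :class:`AtomModel`."""
    import biotite.structure.io as strucio

    try:
        atoms = strucio.load_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyCloudError(f"{path}: structure contains no atoms")
    elements = np.asarray(atoms.element, dtype="U6")
    radii = assign_vdw_radii(elements, default=default_radius)
    return AtomModel(elements, np.asarray(atoms.atom_name, dtype="U6"),
                     np.asarray(atoms.res_id, dtype=int),
                     np.asarray(atoms.res_name, dtype="U6"),
                     np.asarray(atoms.chain_id, dtype="U6"),
                     np.asarray(atoms.coord, dtype=float), radii)


def write_structure(path, model: AtomModel) -> None:
    """Write an :class:`AtomModel` as PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = struc.AtomArray(len(model))
    atoms.coord = model.coords.astype(np.float32)
    atoms.element = model.element
    atoms.atom_name = model.name
    atoms.res_id = model.res_id
    atoms.res_name = model.res_name
    atoms.chain_id = model.chain_id
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path, topology=None) -> LipidTrajectory:
    """Read a multi-frame trajectory (.gro concatenated frames, or .pdb models).

    GRO files are parsed natively (coordinates converted nm -> Angstrom);
    multi-model PDB goes through biotite. XYZ frames are accepted when a
    GRO/PDB ``topology`` supplies the annotations.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".gro":
        return _read_gro(path)
    if suffix == ".pdb":
        return _read_pdb_frames(path)
    if suffix == ".xyz":
        if topology is None:
            raise FormatError("XYZ trajectories need a topology file for "
                              "atom annotations")
        top = read_trajectory(topology)
        coords = _read_xyz_coords(path)
        if coords.shape[1] != top.n_atoms:
            raise FormatError(
                f"XYZ frames have {coords.shape[1]} atoms, topology has "
                f"{top.n_atoms}")
        return LipidTrajectory(coords, top.names, top.res_id, top.res_name,
                               box=None, chain_id=top.chain_id)
    raise FormatError(f"unsupported trajectory format: {suffix}")


def _read_gro(path) -> LipidTrajectory:
    frames, times, boxes = [], [], []
    names = res_ids = res_names = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"{path}:{i + 2}: expected atom count") from exc
        atom_lines = lines[i + 2:i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        f_names, f_rid, f_rname, coords = [], [], [], []
        for j, ln in enumerate(atom_lines):
            try:
                f_rid.append(int(ln[0:5]))
                f_rname.append(ln[5:10].strip())
                f_names.append(ln[10:15].strip())
                coords.append([float(ln[20:28]), float(ln[28:36]),
                               float(ln[36:44])])
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}:{i + 3 + j}: unparsable GRO atom record") from exc
        box_line = lines[i + 2 + natoms].split()
        boxes.append([float(v) * 10.0 for v in box_line[:3]])
        t = float(title.split("t=")[1].split()[0]) if "t=" in title else len(frames)
        times.append(t)
        frames.append(np.asarray(coords) * 10.0)  # nm -> Angstrom
        if names is None:
            names, res_ids, res_names = f_names, f_rid, f_rname
        elif len(f_names) != len(names):
            raise FormatError(
                f"{path}: frame {len(frames)} has {len(f_names)} atoms, "
                f"expected {len(names)}")
        i += natoms + 3
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return LipidTrajectory(np.stack(frames), names, res_ids, res_names,
                           times=np.asarray(times), box=np.asarray(boxes))


def write_gro(path, traj: LipidTrajectory) -> None:
    """Write a trajectory as concatenated GRO frames (nm units on disk)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"memlens trajectory, t= {traj.times[f]:.4f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a] / 10.0
                fh.write(f"{traj.res_id[a] % 100000:5d}"
                         f"{traj.res_name[a]:<5.5s}{traj.names[a]:>5.5s}"
                         f"{(a + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            box = (traj.box[f] / 10.0 if traj.box is not None
                   else np.zeros(3))
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def _read_pdb_frames(path) -> LipidTrajectory:
    import biotite.structure.io.pdb as pdb

    try:
        f = pdb.PDBFile.read(str(path))
        stack = f.get_structure()  # AtomArrayStack over MODEL records
    except Exception as exc:
        raise FormatError(f"cannot parse PDB trajectory {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return LipidTrajectory(coords, np.asarray(stack.atom_name, dtype="U6"),
                           np.asarray(stack.res_id, dtype=int),
                           np.asarray(stack.res_name, dtype="U6"),
                           chain_id=np.asarray(stack.chain_id, dtype="U6"))


def _read_xyz_coords(path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: expected atom count") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated XYZ frame at line {i + 1}")
        coords = [[float(v) for v in ln.split()[1:4]] for ln in block]
        frames.append(coords)
        i += n + 2
    return np.asarray(frames, dtype=float)


def write_xyz(path, traj: LipidTrajectory) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.4f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{traj.names[a][0]:<2s} {x:12.5f} {y:12.5f} "
                         f"{z:12.5f}\n")
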