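"""Trajectory event analyses: lipid flip-flops, lateral-gate distance,
Kabsch superposition RMSD, and hydrogen-bond occupancy.

Flip-flop detection assigns every lipid to a leaflet by the sign of its
head height relative to the midplane (per-frame mean head height) with a
hysteresis dead zone: a label only changes once the head clears
``midplane +/- gap/2``, so thermal wobble at the midplane is not counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .io import AtomModel, LipidTrajectory


@dataclass(frozen=True)
class FlipEvent:
    lipid_id: int
    frame: int
    direction: str               # "up" or "down"
    position: tuple = None       # lateral (x, y) at the event frame


@dataclass
class EventLog:
    """Detected (or generated ground-truth) flip-flop events."""

    events: list
    n_frames: int
    times: np.ndarray = None

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        for ev in self.events:
            if not (0 <= ev.frame < self.n_frames):
                raise ParameterError(
                    f"event frame {ev.frame} outside trajectory")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def cumulative_curve(self) -> np.ndarray:
        """Cumulative event count per frame (non-decreasing)."""
        counts = np.zeros(self.n_frames, dtype=int)
        for ev in self.events:
            counts[ev.frame] += 1
        return np.cumsum(counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(ev.lipid_id, ev.frame, ev.direction,
              *(ev.position or (np.nan, np.nan))) for ev in self.events],
            columns=["lipid_id", "frame", "direction", "x", "y"])


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor-acceptor distance cutoff,
    plus a D-H...A angle cutoff applied only when hydrogens are present."""

    d_DA_max: float = 3.5
    angle_DHA_min: float = 150.0
    heavy_atom_only: bool = False

    def __post_init__(self) -> None:
        if self.d_DA_max <= 0:
            raise ParameterError("d_DA_max must be positive")
        if not (0 <= self.angle_DHA_min <= 180):
            raise ParameterError("angle_DHA_min must be in [0, 180]")


@dataclass
class GateSelection:
    """Residue ranges of the two lateral-gate helices (TM2 / TM7)."""

    tm2_chain: str
    tm2_residues: tuple          # (first, last) inclusive
    tm7_chain: str
    tm7_residues: tuple
    atom_names: tuple = ("CA",)


# ---------------------------------------------------------------------------
# leaflet assignment and flip-flop detection
# ---------------------------------------------------------------------------

def assign_leaflets(z_heads, midplane: float, hysteresis_gap: float = 10.0,
                    prev_labels=None) -> np.ndarray:
    """Leaflet labels (+1 upper / -1 lower) with hysteresis.

    Without previous labels, the sign of (z - midplane) decides. With them,
    a label flips only once the head crosses beyond midplane +/- gap/2.
    """
    z = np.asarray(z_heads, dtype=float)
    if z.size == 0:
        raise SelectionError("no lipid heads to assign")
    if prev_labels is None:
        return np.where(z >= midplane, 1, -1)
    labels = np.asarray(prev_labels).copy()
    half = hysteresis_gap / 2.0
    labels[z > midplane + half] = 1
    labels[z < midplane - half] = -1
    return labels


def detect_flipflops(traj: LipidTrajectory, hysteresis_gap: float = 10.0,
                     head_name: str = "P") -> EventLog:
    """Detect completed leaflet changes of every lipid head.

    The midplane is re-estimated each frame as the mean head height (robust
    to slow drift); one event is recorded per completed label change, with
    the head's lateral position at the event frame.
    """
    if traj.n_frames < 2:
        raise ParameterError("flip-flop detection needs >= 2 frames")
    heads = traj.head_indices(head_name)
    if len(heads) == 0:
        raise SelectionError(f"no head particles named {head_name!r}")
    lipid_ids = traj.res_id[heads]
    z0 = traj.coords[0, heads, 2]
    labels = assign_leaflets(z0, float(z0.mean()))
    events = []
    for f in range(1, traj.n_frames):
        pos = traj.coords[f, heads]
        midplane = float(pos[:, 2].mean())
        new = assign_leaflets(pos[:, 2], midplane, hysteresis_gap, labels)
        changed = np.flatnonzero(new != labels)
        for i in changed:
            events.append(FlipEvent(
                lipid_id=int(lipid_ids[i]), frame=f,
                direction="up" if new[i] > 0 else "down",
                position=(float(pos[i, 0]), float(pos[i, 1]))))
        labels = new
    return EventLog(events, n_frames=traj.n_frames, times=traj.times)


# ---------------------------------------------------------------------------
# lateral gate distance
# ---------------------------------------------------------------------------

def _resolve_range(traj, chain, residues, atom_names):
    res_ids = np.arange(residues[0], residues[1] + 1)
    mask = ((traj.chain_id == chain)
            & np.isin(traj.res_id, res_ids)
            & np.isin(traj.names, np.asarray(list(atom_names))))
    if not mask.any():
        present = set(traj.res_id[traj.chain_id == chain])
        missing = [r for r in res_ids if r not in present]
        raise SelectionError(
            f"selection {chain}:{residues[0]}-{residues[1]} resolved to no "
            f"atoms (missing residues: {missing[:10]})")
    return np.flatnonzero(mask)


def gate_distance(traj: LipidTrajectory, sel: GateSelection) -> np.ndarray:
    """Per-frame distance between the centers of geometry of TM2 and TM7."""
    i2 = _resolve_range(traj, sel.tm2_chain, sel.tm2_residues, sel.atom_names)
    i7 = _resolve_range(traj, sel.tm7_chain, sel.tm7_residues, sel.atom_names)
    if np.intersect1d(i2, i7).size:
        raise SelectionError("TM2 and TM7 selections overlap")
    c2 = traj.coords[:, i2].mean(axis=1)
    c7 = traj.coords[:, i7].mean(axis=1)
    return np.linalg.norm(c2 - c7, axis=1)


# ---------------------------------------------------------------------------
# Kabsch superposition RMSD
# ---------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_rmsd(traj: LipidTrajectory, reference, selection=None) -> np.ndarray:
    """Per-frame RMSD after optimal rigid-body (Kabsch) superposition."""
    ref = (reference.coords if isinstance(reference, AtomModel)
           else np.asarray(reference, dtype=float))
    if selection is None:
        sel = np.arange(traj.n_atoms)
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    if ref.shape != (len(sel), 3):
        raise SelectionError(
            f"reference has {len(ref)} atoms, selection has {len(sel)}")
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        P = traj.coords[f, sel]
        P_c = P - P.mean(axis=0)
        R = kabsch_rotation(P_c, ref_c)
        diff = P_c @ R.T - ref_c
        out[f] = np.sqrt((diff ** 2).sum() / len(sel))
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _find_hydrogens(traj, donor_idx, max_dh=1.25):
    """Hydrogens covalently attached to each donor (frame-0 geometry)."""
    h_mask = np.array([n.startswith("H") for n in traj.names])
    h_idx = np.flatnonzero(h_mask)
    attached = {}
    if len(h_idx):
        from scipy.spatial import cKDTree
        tree = cKDTree(traj.coords[0, h_idx])
        for d in donor_idx:
            near = tree.query_ball_point(traj.coords[0, d], max_dh)
            attached[int(d)] = [int(h_idx[i]) for i in near]
    else:
        attached = {int(d): [] for d in donor_idx}
    return attached


def hbond_occupancy(traj: LipidTrajectory, donors, acceptors,
                    crit: HBondCriteria = None) -> pd.DataFrame:
    """Fraction of frames each donor-acceptor pair is hydrogen bonded.

    A bond is present when d(D, A) <= d_DA_max and, if the donor carries at
    least one hydrogen (and ``heavy_atom_only`` is off), some D-H...A angle
    is >= angle_DHA_min. Donors/acceptors are atom indices into the
    trajectory.
    """
    crit = crit or HBondCriteria()
    donors = np.atleast_1d(np.asarray(donors, dtype=int))
    acceptors = np.atleast_1d(np.asarray(acceptors, dtype=int))
    if donors.size == 0 or acceptors.size == 0:
        raise SelectionError("empty donor or acceptor selection")
    attached = ({} if crit.heavy_atom_only
                else _find_hydrogens(traj, donors))
    rows = []
    cos_min = np.cos(np.deg2rad(crit.angle_DHA_min))
    for d in donors:
        hs = attached.get(int(d), [])
        for a in acceptors:
            if a == d:
                continue
            dvec = traj.coords[:, a] - traj.coords[:, d]
            dist = np.linalg.norm(dvec, axis=1)
            present = dist <= crit.d_DA_max
            if hs and not crit.heavy_atom_only:
                ang_ok = np.zeros(traj.n_frames, dtype=bool)
                for h in hs:
                    hd = traj.coords[:, d] - traj.coords[:, h]
                    ha = traj.coords[:, a] - traj.coords[:, h]
                    cos = (np.sum(hd * ha, axis=1)
                           / (np.linalg.norm(hd, axis=1)
                              * np.linalg.norm(ha, axis=1)))
                    # angle D-H...A >= cutoff  <=>  cos(angle) <= cos(cutoff)
                    ang_ok |= cos <= cos_min
                present = present & ang_ok
            rows.append((int(d), int(a), traj.names[d], traj.names[a],
                         int(traj.res_id[d]), int(traj.res_id[a]),
                         float(present.mean())))
    return pd.DataFrame(rows, columns=["donor", "acceptor", "donor_name",
                                       "acceptor_name", "donor_res",
                                       "acceptor_res", "occupancy"])
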