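"""Synthetic ground-truth generators for every pipeline stage.

Everything downstream — surface fitting, curvature, thickness, order
parameters, flip-flop detection, SASA — is validated against data produced
here with exactly known parameters: scattered samples of analytic surfaces,
"lensed" bilayers whose lower leaflet bulges so the membrane thins, lipid
trajectories with prescribed acyl-chain order and Poisson flip-flop events,
and toy atomic structures (ideal helices, hydrogen-bond pairs, spheres).

All generators are deterministic given their seed. Lateral sampling is
uniform-random rather than on a lattice, to mimic the irregular voxel
positions a membrane segmentation produces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import EventLog, FlipEvent
from .errors import GeometryError, ParameterError
from .io import AtomModel, LeafletPointCloud, LipidTrajectory

_SQRT1_2 = np.sqrt(0.5)

SURFACE_KINDS = ("plane", "sphere_cap", "gaussian_bump", "microsome_patch")


@dataclass
class SurfaceSpec:
    """An analytic leaflet surface plus sampling instructions.

    kind:
        ``plane``           z = z0
        ``sphere_cap``      upward sphere cap, apex at (0, 0, z0), radius R
        ``gaussian_bump``   z = z0 + A exp(-r^2 / 2 sigma^2)
        ``microsome_patch`` sphere-cap background of radius R_bg plus a
                            local Gaussian bump — the geometry of a membrane
                            patch on a large vesicle with localized curvature
                            at a protein site
    params: geometric parameters in Angstrom (R, A, sigma, R_bg, z0).
    extent: lateral box edge (points are drawn in [-extent/2, extent/2]^2).
    density: points per Angstrom^2.
    noise_sd: additive Gaussian noise on z, Angstrom.
    """

    kind: str
    params: dict = field(default_factory=dict)
    extent: float = 200.0
    density: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SURFACE_KINDS:
            raise ParameterError(f"unknown surface kind {self.kind!r}")
        if self.density <= 0 or self.extent <= 0:
            raise ParameterError("density and extent must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        for key, radius in (("sphere_cap", "R"), ("microsome_patch", "R_bg")):
            if self.kind == key:
                R = float(self.params[radius])
                if self.extent >= 2 * R or self.extent * _SQRT1_2 >= R:
                    raise GeometryError(
                        f"extent {self.extent} too large for {radius}={R}: "
                        "the cap is not a height function over the box")

    # -- analytic surface ---------------------------------------------------

    def analytic_z(self, x, y) -> np.ndarray:
        """Noise-free surface height at lateral positions (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.params
        z0 = float(p.get("z0", 0.0))
        r2 = x * x + y * y
        if self.kind == "plane":
            return np.broadcast_to(z0, r2.shape).copy() if r2.ndim else z0 + 0.0
        if self.kind == "sphere_cap":
            R = float(p["R"])
            return z0 + np.sqrt(R * R - r2) - R
        if self.kind == "gaussian_bump":
            A, sigma = float(p["A"]), float(p["sigma"])
            return z0 + A * np.exp(-r2 / (2 * sigma * sigma))
        # microsome_patch
        R = float(p["R_bg"])
        A, sigma = float(p.get("A", 0.0)), float(p.get("sigma", 40.0))
        return (z0 + np.sqrt(R * R - r2) - R
                + A * np.exp(-r2 / (2 * sigma * sigma)))


@dataclass
class BilayerSpec:
    """Paired leaflet surfaces; ``upper`` must lie above ``lower`` everywhere."""

    upper: SurfaceSpec
    lower: SurfaceSpec
    nominal_thickness: float = 34.0


def lensed_bilayer_spec(nominal_thickness: float = 34.0,
                        bump_amplitude: float = 5.0,
                        bump_sigma: float = 40.0,
                        extent: float = 200.0,
                        density: float = 0.25,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> BilayerSpec:
    """Flat upper leaflet; lower leaflet bulges up by ``bump_amplitude``.

    Thickness = upper - lower is ``nominal_thickness`` in the far field and
    ``nominal_thickness - bump_amplitude`` at the bump center — the
    simultaneous curving-and-thinning ("lensing") geometry.
    """
    half = nominal_thickness / 2.0
    upper = SurfaceSpec("plane", {"z0": +half}, extent=extent,
                        density=density, noise_sd=noise_sd, seed=seed)
    lower = SurfaceSpec("gaussian_bump",
                        {"z0": -half, "A": bump_amplitude, "sigma": bump_sigma},
                        extent=extent, density=density, noise_sd=noise_sd,
                        seed=seed + 1)
    return BilayerSpec(upper, lower, nominal_thickness)


@dataclass
class TrajectorySpec:
    """Parameters for a synthetic lipid trajectory with known ground truth.

    target_SCD: expectation of the deuterium order parameter
        <(3 cos^2 theta - 1)/2> of every C-H bond, in [-0.5, 1].
    flip_rate: per-lipid per-frame probability of a flip-flop event.
    hysteresis_gap: vertical dead zone (Angstrom) around the midplane that a
        head must clear for a leaflet change to count; heads sit well outside
        it so every generated jump is a true crossing.
    leaflet_offset: |z| of head particles from the midplane, Angstrom.
    """

    n_lipids: int = 200
    n_frames: int = 100
    dt: float = 1.0
    target_SCD: float = 0.20
    flip_rate: float = 0.0
    hysteresis_gap: float = 10.0
    box: tuple = (200.0, 200.0, 100.0)
    leaflet_offset: float = 17.0
    jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_rate <= 1.0):
            raise ParameterError("flip_rate must be in [0, 1]")
        if not (-0.5 <= self.target_SCD <= 1.0):
            raise ParameterError("target_SCD must be in [-0.5, 1]")
        if self.n_lipids < 1 or self.n_frames < 1:
            raise ParameterError("n_lipids and n_frames must be >= 1")
        if self.leaflet_offset <= self.hysteresis_gap / 2:
            raise ParameterError(
                "leaflet_offset must exceed hysteresis_gap/2 so heads sit "
                "outside the dead zone")


# ---------------------------------------------------------------------------
# surface clouds
# ---------------------------------------------------------------------------

def gen_surface_cloud(spec: SurfaceSpec,
                      leaflet_label: str = "upper") -> LeafletPointCloud:
    """Sample a scattered point cloud of the analytic surface.

    Lateral positions are uniform over the box at the requested density;
    z is the analytic height plus N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(3, int(round(spec.density * spec.extent ** 2)))
    xy = rng.uniform(-spec.extent / 2, spec.extent / 2, size=(n, 2))
    z = spec.analytic_z(xy[:, 0], xy[:, 1])
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=n)
    coords = np.column_stack([xy, z])
    return LeafletPointCloud(coords, leaflet_label=leaflet_label,
                             provenance=f"synthetic {spec.kind} seed={spec.seed}")


def gen_lensed_bilayer(spec: BilayerSpec):
    """Two leaflet clouds; raises :class:`GeometryError` if they overlap."""
    # check the analytic surfaces on a shared grid before sampling
    ext = min(spec.upper.extent, spec.lower.extent)
    g = np.linspace(-ext / 2, ext / 2, 101)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    gap = spec.upper.analytic_z(gx, gy) - spec.lower.analytic_z(gx, gy)
    if np.min(gap) <= 0:
        raise GeometryError(
            f"leaflet surfaces overlap (min separation {np.min(gap):.3f} A)")
    upper = gen_surface_cloud(spec.upper, leaflet_label="upper")
    lower = gen_surface_cloud(spec.lower, leaflet_label="lower")
    return upper, lower


# ---------------------------------------------------------------------------
# lipid trajectories
# ---------------------------------------------------------------------------

_CARBONS = tuple(range(2, 16))     # palmitate chain carbons carrying 2 H each
_CH_BOND = 1.09                    # Angstrom
_CHAIN_STEP = 1.0                  # Angstrom per carbon toward the midplane


def _atom_names():
    names = ["P"]
    for k in _CARBONS:
        names += [f"C{k}", f"H{k}A", f"H{k}B"]
    return names


def _ch_directions(rng, shape, target_scd):
    """Unit C-H vectors from a two-state mixture hitting target_SCD exactly
    in expectation: an oriented state (parallel for positive targets,
    in-plane for negative) mixed with an isotropic state."""
    n = int(np.prod(shape))
    u = np.empty((n, 3))
    if target_scd >= 0:
        p_state = target_scd          # P2 = 1 in the aligned state
        aligned = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:
        p_state = -2.0 * target_scd   # P2 = -1/2 in the in-plane state
        phi = rng.uniform(0, 2 * np.pi, n)
        aligned = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    pick = rng.random(n) < p_state
    # isotropic unit vectors for the remainder
    costh = rng.uniform(-1, 1, n)
    sinth = np.sqrt(1 - costh ** 2)
    phi2 = rng.uniform(0, 2 * np.pi, n)
    iso = np.column_stack([sinth * np.cos(phi2), sinth * np.sin(phi2), costh])
    u[pick] = aligned[pick]
    u[~pick] = iso[~pick]
    return u.reshape(*shape, 3)


def gen_lipid_trajectory(spec: TrajectorySpec):
    """Build a lipid trajectory with known order and flip-flop ground truth.

    Each lipid is a head particle ``P`` plus chain carbons C2..C15, each
    carrying two explicit hydrogens whose C-H orientations are drawn so that
    <P2(cos theta)> equals ``target_SCD``. Flip-flops are instantaneous
    mirror jumps across the midplane (z -> -z for the whole lipid), drawn
    per lipid per frame with probability ``flip_rate``; the realized events
    are returned as the true :class:`EventLog`.
    """
    rng = np.random.default_rng(spec.seed)
    nl, nf = spec.n_lipids, spec.n_frames
    names_per = _atom_names()
    apl = len(names_per)                       # atoms per lipid
    names = np.array(names_per * nl)
    res_id = np.repeat(np.arange(1, nl + 1), apl)
    res_name = np.array(["POPC"] * apl * nl)

    # static lateral positions and initial leaflet (+1 upper / -1 lower)
    lateral = rng.uniform(0, [spec.box[0], spec.box[1]], size=(nl, 2))
    side = np.where(np.arange(nl) % 2 == 0, 1.0, -1.0)

    # flip schedule: Bernoulli(flip_rate) per lipid per frame (frames >= 1)
    events = []
    flips = np.zeros((nf, nl), dtype=bool)
    if spec.flip_rate > 0 and nf > 1:
        flips[1:] = rng.random((nf - 1, nl)) < spec.flip_rate

    coords = np.empty((nf, apl * nl, 3))
    times = np.arange(nf, dtype=float) * spec.dt
    box = np.tile(np.asarray(spec.box, dtype=float), (nf, 1))
    carbons = np.asarray(_CARBONS)
    chain_drop = (carbons - 1) * _CHAIN_STEP   # distance below the head

    cur = side.copy()
    for f in range(nf):
        flipped = flips[f]
        if flipped.any():
            for lip in np.flatnonzero(flipped):
                cur[lip] = -cur[lip]
                events.append(FlipEvent(
                    lipid_id=lip + 1, frame=f,
                    direction="up" if cur[lip] > 0 else "down",
                    position=(lateral[lip, 0], lateral[lip, 1])))
        head_xy = lateral + rng.normal(0, spec.jitter_sd, size=(nl, 2))
        head_z = cur * spec.leaflet_offset + rng.normal(
            0, spec.jitter_sd, size=nl)
        u = _ch_directions(rng, (nl, len(carbons), 2), spec.target_SCD)
        frame = coords[f].reshape(nl, apl, 3)
        frame[:, 0, :2] = head_xy
        frame[:, 0, 2] = head_z
        # chain extends from the head toward the midplane
        cz = head_z[:, None] - cur[:, None] * chain_drop[None, :]
        for ci in range(len(carbons)):
            base = 1 + 3 * ci
            frame[:, base, :2] = head_xy
            frame[:, base, 2] = cz[:, ci]
            for h in range(2):
                frame[:, base + 1 + h] = frame[:, base] + _CH_BOND * u[:, ci, h]
    traj = LipidTrajectory(coords, names, res_id, res_name,
                           times=times, box=box)
    log = EventLog(events, n_frames=nf, times=times)
    return traj, log


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def gen_toy_structure(kind: str, **params) -> AtomModel:
    """Deterministic toy atomic models for gate-distance, RMSD, H-bond and
    SASA tests.

    kinds:
        ``single_atom``  one atom; ``r`` sets its vdW radius.
        ``two_helices``  two ideal alpha-helices (rise 1.5 A/residue,
                         100 deg/residue, 2.3 A backbone radius), axes along
                         z, separated by ``separation`` along x; chains A/B.
        ``hbond_pair``   collinear N-H...O geometry with donor-acceptor
                         distance ``d_DA`` (default 2.9 A).
        ``sphere_pair``  two atoms of radius ``r`` separated by ``d``.
    """
    if kind == "single_atom":
        r = float(params.get("r", 1.9))
        return AtomModel(["C"], ["X1"], [1], ["TOY"], ["A"],
                         [[0.0, 0.0, 0.0]], [r])
    if kind == "two_helices":
        sep = float(params.get("separation", 12.0))
        n_res = int(params.get("n_res", 20))
        helix_r, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
        elements, names, rids, rnames, chains, coords = [], [], [], [], [], []
        for h, (x0, chain) in enumerate(((-sep / 2, "A"), (sep / 2, "B"))):
            for i in range(n_res):
                ang = i * twist
                coords.append([x0 + helix_r * np.cos(ang),
                               helix_r * np.sin(ang),
                               i * rise - (n_res - 1) * rise / 2])
                elements.append("C")
                names.append("CA")
                rids.append(i + 1)
                rnames.append("ALA")
                chains.append(chain)
        return AtomModel(elements, names, rids, rnames, chains, coords)
    if kind == "hbond_pair":
        d_da = float(params.get("d_DA", 2.9))
        coords = [[0.0, 0.0, 0.0],        # donor N
                  [1.0, 0.0, 0.0],        # its H, collinear with the acceptor
                  [d_da, 0.0, 0.0]]       # acceptor O
        return AtomModel(["N", "H", "O"], ["N", "H", "O"], [1, 1, 2],
                         ["ASN", "ASN", "ASP"], ["A", "A", "B"], coords)
    if kind == "sphere_pair":
        r = float(params.get("r", 1.9))
        d = float(params.get("d", 3.0))
        return AtomModel(["C", "C"], ["X1", "X2"], [1, 2], ["TOY", "TOY"],
                         ["A", "B"], [[0.0, 0.0, 0.0], [d, 0.0, 0.0]],
                         [r, r])
    raise ParameterError(f"unknown toy structure kind {kind!r}")
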