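# Methods

`memlens` quantifies how a membrane-embedded protein complex remodels its
host bilayer: local curving ("lensing"), thinning, acyl-chain disordering,
and enhanced lipid flip-flop. The package operates on two kinds of input —
leaflet point sets derived from segmented cryo-ET density maps, and
annotated MD-style trajectories — and every stage can be exercised against
synthetic data with exactly known parameters.

## Leaflet surface reconstruction

A leaflet is represented as a height function z(x, y) over a regular
lateral grid (default spacing 4 Å, roughly the voxel scale of a membrane
segmentation). Reconstruction is two-step:

1. **Scattered interpolation.** The lateral positions of the input points
   are Delaunay-triangulated and z is interpolated piecewise-linearly onto
   the grid (`scipy.interpolate.LinearNDInterpolator`). Nodes outside the
   convex hull are marked invalid. Linear interpolation is exact for
   planes; its error on a smooth surface is bounded per triangle by the
   surface curvature and triangle size, which the tests verify with a
   brute-force per-triangle oracle.
2. **LOESS smoothing.** At each grid node, the nearest
   `ceil(span_fraction * N)` samples (k-nearest by count, not a fixed
   radius) are fit with a bivariate polynomial of degree 1 or 2 under
   tricube weights `w = (1 - (d/d_max)^3)^3`, and the fit is evaluated at
   the node. Defaults: span 0.20, degree 2. Degree-2 LOESS reproduces any
   global quadratic surface exactly; this is the key correctness anchor and
   is tested to 1e-6 Å. Smoothing is applied to the gridded samples
   produced by step 1 (a points-direct mode is also exposed).

Numerical safeguards: local coordinates are centered on the node and
scaled by the neighborhood radius; if the degree-2 normal-matrix condition
number exceeds 1e10 the fit falls back to degree 1, and a node is
invalidated (not fatal) if that also fails. With `span_fraction = 1` the
tricube distance weights remain active, so the result coincides with an
unweighted global quadratic fit only on data a quadratic fits exactly;
the tests assert the identity in that regime.

**Resolution trade-off.** The k-nearest-neighbor span couples the
smoothing length to the analyzed patch: for a uniformly sampled square
patch of edge L, a 20% span gives a neighborhood radius of about 0.25 L
regardless of sampling density. Features narrower than that radius are
attenuated. The package therefore analyzes two-scale geometry (a large
background vesicle plus a localized protein-induced bump) in two passes:
the whole patch for the background radius, and a cropped window around the
protein (the span then being 20% of the points in that window) for the
local radius. This keeps the span definition fixed while letting each
scale be resolved; both passes recover their analytic radii within ~5% in
the acceptance checks.

## Curvature and thickness

Mean and Gaussian curvature come from central finite differences of the
height field (`numpy.gradient`, one-sided stencils at array borders):

    H = [(1 + z_x^2) z_yy - 2 z_x z_y z_xy + (1 + z_y^2) z_xx]
        / [2 (1 + z_x^2 + z_y^2)^(3/2)]
    K = (z_xx z_yy - z_xy^2) / (1 + z_x^2 + z_y^2)^2

The surface normal is fixed toward +z (the cytosolic side), so a bulge
toward +z has negative H at its apex; a lumenal leaflet bulging toward the
cytosol therefore shows the negative mean curvature conventionally
reported for such geometry. A regional radius of curvature is
`R = 1 / |mean H over the region|` — averaging H before inverting, which
is stable when H fluctuates around small values, rather than averaging
1/|H|. Cells adjacent to invalid neighbors inherit NaN from the stencil
and are masked.

For a free-floating patch (a bicelle) that need not be a height function
of a fixed frame, a sphere is fit directly to the 3-D points: the linear
algebraic (Coope) formulation solved by least squares, refined by one
Gauss-Newton pass on the geometric residuals |p - c| - R. Exact sphere
points are recovered to machine precision; 5,000 points with 1 Å noise
recover the radius within 1%.

Local thickness is the vertical difference z_upper - z_lower of the two
leaflet fields on a shared grid (the lower field is bilinearly resampled
if the grids differ). Thickness along the local normal is not the default
because the leaflet difference on height fields is the standard map-based
definition; for the gentle slopes involved (|∇z| ≪ 1) the distinction is
second order.

## Distribution statistics

Thickness and order distributions are summarized with a 1-D Gaussian
mixture fitted by EM: k-means++ initialization, log-domain E-step,
closed-form M-step, convergence when the log-likelihood gain falls below
`tol` (1e-8 relative). The log-likelihood is asserted non-decreasing at
every iteration. A component whose sd collapses below 1e-6 of the data sd
is pruned with a warning. Components are reported sorted by decreasing
mean, so for a thinned membrane the first component is the unperturbed
population. Fitting k=2 to unimodal data is a documented degeneracy: the
two components overlap heavily while their pooled moments match the data;
`select_k_by_bic` chooses k in {1, 2} by BIC when model selection is
wanted. EM initialization uses a fixed default seed (0); all stochastic
entry points accept a seed.

## Order parameters

The deuterium order parameter of a chain carbon is
`S_CD = <(3 cos^2 theta - 1)/2>` with theta the C–H angle to the membrane
normal (+z), averaged over lipids, frames and hydrogens. Carbons 2–15 of
the palmitate chain are analyzed by default; the chain average is reported
as a magnitude with the signed value retained, matching the convention of
plotting positive S_CD (≈ 0.2 for an ordered fluid bilayer). Standard
errors are computed over per-lipid averages, the natural independent unit.
Local order maps bin each lipid's per-frame chain average by the lateral
cell of its head particle.

## Trajectory events

**Flip-flops.** Each lipid head is assigned to a leaflet by the sign of
z - midplane, with the midplane re-estimated every frame as the mean head
height (robust to slow drift). A hysteresis dead zone of `gap` (default
10 Å, about half a leaflet) around the midplane prevents thermal wobble
from counting as translocation: a label changes only when the head clears
midplane ± gap/2. One event is recorded per completed label change,
together with its lateral position, enabling spatial attribution of
events to protein sites. Doubling the gap can only remove events
(monotonicity, property-tested).

**Gate distance** is the per-frame Euclidean distance between the centers
of geometry of two user-specified helix selections (chain + residue range,
Cα by default). The residue ranges are mandatory input, as there is no
universal definition of the helix boundaries.

**RMSD** uses Kabsch superposition (SVD with the determinant correction
enforcing a proper rotation) before the root-mean-square deviation; it is
invariant to any proper rigid transform of the mobile frame to < 1e-9 Å.

**Hydrogen bonds.** A donor-acceptor pair is bonded in a frame when
d(D, A) ≤ 3.5 Å and, if the donor carries hydrogens, some D–H···A angle is
≥ 150°; hydrogens are located once from frame-0 covalent geometry
(< 1.25 Å from the donor). Occupancy is the bonded fraction of frames. A
heavy-atom-only mode drops the angle criterion for hydrogen-free models.

## SASA and interfaces

Shrake-Rupley with a golden-spiral (Fibonacci) point set, default 960
points per atom and probe radius 1.4 Å; radii from a Bondi-style table
with a configurable default (1.70 Å) for unknown elements, hydrogens
ignored by default since deposited models often lack them. The buried
interface between two groups is SASA(A) + SASA(B) - SASA(A∪B), reported
both as the total and halved; the halved (per-side) value is the primary
number since single-side areas are the more common convention. An isolated
atom reproduces 4π(r + probe)² within 0.5% at 960 points; overlapping
pairs match the spherical-cap closed form within 1%.

## Synthetic ground truth

The generators define the conditions every recovery check runs under:

* **Surface clouds** — plane, sphere cap, Gaussian bump, and
  "microsome patch" (background sphere cap of radius R_bg plus a local
  bump). Lateral sampling is uniform-random, not a lattice, to mimic
  segmentation voxel irregularity and stress the scattered interpolation.
  Noise is additive Gaussian on z. Defaults used in the acceptance checks:
  sphere cap R = 320 Å with 1 Å noise (~5,000 points); microsome patch
  R_bg = 1,300 Å, bump sigma = 40 Å and amplitude 6.2 Å, chosen so the
  region-mean curvature within 40 Å of the center corresponds to a ≈320 Å
  radius — the geometry observed for a translocon-scale inclusion on a
  microsome-sized vesicle.
* **Lensed bilayer** — flat upper leaflet at +17 Å, lower leaflet with a
  +5 Å Gaussian bump at -17 Å: thickness 34 Å far field thinning to 29 Å
  at the center.
* **Lipid trajectories** — each lipid is a head particle plus chain
  carbons C2–C15 carrying two explicit hydrogens. C–H orientations come
  from a two-state mixture (an oriented state blended with an isotropic
  state) whose mixing weight hits the target S_CD exactly in expectation —
  the simplest exactly solvable order model. Flip-flops are instantaneous
  mirror jumps across the midplane drawn per lipid per frame with the
  prescribed probability, and the realized events are returned as ground
  truth, so detector checks can demand exact agreement. Positional jitter
  (sd 0.3 Å) is kept far below the hysteresis half-gap.
* **Toy structures** — ideal α-helix pairs (rise 1.5 Å/residue,
  100°/residue), collinear N–H···O hydrogen-bond pairs, and single/paired
  spheres for SASA.

What the generators deliberately omit: thermal surface undulations with a
realistic spectrum, finite flip-flop transit times, protein-excluded
areas in the point clouds, segmentation artifacts (anisotropic noise,
missing wedges), and chain conformational coupling between neighboring
carbons. Passing the recovery checks therefore demonstrates correctness
of the estimators under clean, known conditions — not robustness to every
artifact of real cryo-ET or MD data.

## Problem sizes and determinism

The recovery analyses run at desk scale: ~5,000–8,000 surface points,
500 lipids × 100 frames for order parameters, 200 lipids × 2,000 frames
for flip-flop statistics (expected count ≈ 100, Poisson-distributed),
10⁵ samples for mixture fits. All generators and stochastic fits are
deterministic given their seeds; the pipelines write a hash of the
resolved configuration into every summary and re-running a config
reproduces the summary byte-identically.

## Known limitations

* Curvature at the border of the valid region uses one-sided stencils and
  inherits NaN from invalid neighbors; regional averages should exclude
  the outermost cells when precision matters (the two-scale analysis
  does).
* The LOESS span couples resolution to patch size (see above); very
  localized features inside a large patch require the windowed pass.
* Leaflet splitting of a single merged membrane cloud is a deliberately
  simple PCA-sign fallback; curved or closed membranes should be split
  upstream by the segmentation tool.
* The GRO reader/writer rounds coordinates to the format's 0.001 nm
  precision (0.01 Å).
* Thickness distributions pool per-frame, per-cell leaflet differences;
  time-averaged-field alternatives would give narrower distributions.
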