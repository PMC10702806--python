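# memlens

Quantitative analysis of protein-induced membrane remodeling — the
"lensing" (simultaneous local curving and thinning) that a large
membrane-embedded complex such as the Sec61/TRAP translocon imposes on its
host bilayer.

The package is for structural biologists and simulators who have either
(a) leaflet point sets segmented from a cryo-ET density map of a
membrane-embedded complex, or (b) MD-style trajectories of a
protein/membrane system, and want reproducible maps and statistics of the
local membrane state around the protein.

## What it computes

**Leaflet surfaces.** Scattered leaflet points are turned into smooth
height fields z(x, y): piecewise-linear interpolation over the Delaunay
triangulation of the lateral positions, followed by LOESS local regression
(tricube weights over the nearest 20% of points, quadratic local
polynomials by default).

**Curvature and thickness.** From a height field,

    H = [(1 + z_x²) z_yy − 2 z_x z_y z_xy + (1 + z_y²) z_xx]
        / [2 (1 + z_x² + z_y²)^{3/2}],
    K = (z_xx z_yy − z_xy²) / (1 + z_x² + z_y² )²,

with the normal toward +z, so a bulge toward the cytosol has negative H. A
regional radius of curvature is R = 1/|⟨H⟩|; a sphere can also be
least-squares fit directly to 3-D points (for bicelle-like patches). Local
thickness is z_upper − z_lower; its distribution is summarized by a
two-component Gaussian mixture fitted by EM, separating the unperturbed
population from the locally thinned one.

**Order and events.** Deuterium order parameters
S_CD = ⟨(3cos²θ − 1)/2⟩ per chain carbon (2–15) and as local lateral maps;
lipid flip-flop detection with a hysteresis criterion around the
per-frame midplane; TM2–TM7 lateral-gate distance; Kabsch-superposed RMSD;
hydrogen-bond occupancy; Shrake-Rupley SASA and buried interface areas.

**Synthetic ground truth.** A first-class generator module produces
scattered samples of analytic surfaces, lensed bilayers, lipid
trajectories with prescribed S_CD and Poisson flip-flop events (the true
event log is returned alongside), and toy helix/H-bond/sphere structures —
so every estimator is validated against known parameters.

## Worked example

Sample a noisy spherical membrane patch (radius 320 Å, 1 Å noise), fit
the surface, and read off the radius of curvature in a 40 Å region:

```sh
$ memlens simulate --kind sphere_cap -p R=320 --extent 150 \
    --density 0.15 --noise-sd 1.0 --seed 2 --out cloud.csv
wrote 3375 points to cloud.csv

$ memlens curvature --points cloud.csv --region-center 0,0 --region-radius 40
{
  "region": {
    "radius_A": 321.5685918977529,
    "mean_H_invA": -0.00310975644138145
  },
  "far_field": {
    "radius_A": 321.3329066488242,
    "mean_H_invA": -0.003112037327359293
  }
}
```

The fitted radius (321.6 Å) recovers the generator's 320 Å within 0.5%
despite 1 Å of noise on every point; the negative mean curvature says the
patch bulges toward +z. The same operations are available as library
calls:

```python
import memlens as m

spec = m.SurfaceSpec("sphere_cap", {"R": 320.0}, extent=150,
                     density=0.15, noise_sd=1.0, seed=2)
cloud = m.gen_surface_cloud(spec)
grid = m.GridSpec.from_extent(150, spacing=2.0, margin=6)
field = m.fit_leaflet(cloud, grid, m.LoessConfig(span_fraction=0.2, degree=2))
radius, mean_H = m.radius_of_curvature(m.mean_curvature_map(field),
                                       center=(0, 0), radius=40)
```

End-to-end runs (`memlens run-cryoet config.yml`,
`memlens run-md config.yml`) take a YAML config naming the inputs, the
lateral center of the protein region, and grid/LOESS settings, and write
height/curvature/thickness maps as CSV plus a deterministic JSON summary
containing a hash of the resolved configuration.

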