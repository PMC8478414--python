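# Methods

## Model

Cells are the Voronoi polygons of mobile generator points ("cell centers")
in the plane.  Every Voronoi vertex is the circumcenter of a trio of
adjacent centers, written in barycentric form `ω = a·r_i + b·r_j + c·r_k`
with weights proportional to `|r_j − r_k|² (r_i − r_j)·(r_i − r_k)` (and
cyclic permutations), normalized by `D = 2 |(r_i − r_j) × (r_j − r_k)|²`.
Cell areas are shoelace sums over the ordered vertex loops, junction
lengths the distances between the two circumcenters flanking a Delaunay
edge.

Each demarcated cell α contributes

```
E_α = ½ K_α (g_α A0_α) (A_α / (g_α A0_α) − 1)² + Σ_{β∈Γ_α} λ l_β
```

Interior cells use stiffness `K` and prestretch `g`; boundary cells (the
outermost demarcated ring) use `rho·K` and `rho_g·g`.  Γ_α contains the
cell's junctions shared with another demarcated cell, so a shared junction
appears in both cells' sums and contributes `2λl` to the total — the stated
default `λ = 15` is interpreted on this convention.  Forces on centers are
exact analytic gradients: the per-vertex energy gradient is propagated
through the circumcenter's dependence on its generating trio by solving the
transposed 2×2 circumcenter system per triangle; they agree with central
finite differences to ~1e−8 relative.

### Units and calibration

Coordinates are dimensionless model units.  The square domain holds a 25×25
jittered lattice (625 cells); the circular pattern is demarcated by
thresholding the center-to-origin distance at 6.23 lattice spacings, which
captures 120–124 cells (≈121 on average) over random seeds, the model
analogue of a 172 µm circular micropattern holding ~121 fibroblasts.

The energy parameters (`K = 1`, `λ = 15`, `λ_out = 20`, `k_b = 0.1`) fix a
length scale: the dimensionless group `λ/(K·ℓ)` (ℓ = lattice spacing)
measures junction tension against area elasticity.  The lattice spacing is
the calibration dial corresponding to "the size ratio between individual
cell and the micropattern".  At spacings below ~200 units tension dominates
(pressure `2λ·dP/dA ≳ K`) and the energy minimum is a degenerate foam —
interior cells crushed onto the numerical core radius, a few inflated
boundary cells — with no phase behavior in `(g, rho)`; the physically
meaningful regime has the tension pressure well below `K`.  The default
spacing of 450 units (mean cell area `A0 ≈ 2.0e5`, tension pressure
`≈ 0.12 K`) was fixed once, from a scan of {224, 300, 450, 600}, as the
midpoint at which all of the model's qualitative claims are robust over
seeds: the radially aligned corner (`g = 0.5, rho = 0.4`) separates boundary
from interior in area, elongation and angle deviation, and the
contractility-only variant (`rho = 1, rho_g = 0.5`) shrinks boundary cells
without radial alignment.

### Confinement protocol

1. Seed a jittered square lattice (uniform jitter ±0.1 lattice spacings per
   axis; seeded, deterministic).  The jitter amplitude is part of the
   calibration: it reproduces the reported 120–124 demarcation spread
   (larger jitter widens the count distribution beyond it).
2. Demarcate the circle (or annulus) by distance threshold; centers far
   outside the pattern (beyond 2.5 spacings) are dropped — they are fixed
   and mechanically irrelevant, and the smaller tessellation speeds the
   relaxation ~2.5×.
3. Round up the border by relaxing the initialization energy: uniform
   `K = 1`, no prestretch, junction tension within the pattern, extra rim
   tension `λ_out` on junctions crossing the pattern border, and a soft
   global penalty `½ k_b A0 (A/A0 − 1)²` keeping the pattern area near its
   seeded value.  Only demarcated centers move; the fixed surroundings pin
   the tiled area through the Voronoi partition (a mobile tension-free
   collar would let the pattern collapse).
4. Fix the exterior centers and the boundary ring (demarcated cells sharing
   a junction with an exterior cell); interior cells stay mobile.

Intrinsic areas `A0_α` remain the *seeded* Voronoi areas throughout (option
`reference_areas="relaxed"` reproduces the alternative convention).  With
the seeded reference the rounded-up state is an equilibrium of the main
energy at `g = rho = 1`, so the null condition stays put; resetting `A0` to
the post-initialization areas would zero the elastic term and let the
then-unbalanced junction tension re-condense the pattern even without
prestretch.

### Relaxation

Explicit-Euler gradient descent (default `dt = 0.02`, gentle step growth
×1.2 capped at 10·dt) with step-halving backtracking: a step is accepted
only if the rebuilt tessellation is valid and the energy does not increase,
which makes the recorded energy trace non-increasing by construction.
Neighbor exchanges (T1 events) happen implicitly through the per-step
Delaunay rebuild.  Termination: maximum movable-center force below `tol`,
or energy stagnation (decrease over the last 200 accepted steps below
`1e−9·(1+|E|)`; `1e−10` for production runs).  The second rule is needed
because tension-dominated minima can sit at topology-change kinks where the
gradient is discontinuous and never vanishes.

Two numerical regularizations keep the center → tessellation map well
conditioned, both small on the cell scale:

* junction lengths enter the tension energy as `sqrt(l² + ε²) − ε` with
  `ε = 4.5` (1 % of the cell diameter), smoothing the energy through
  zero-length junctions and keeping it continuous across topology flips;
* adjacent generators closer than `135` units (30 % of the lattice spacing)
  feel a soft quadratic repulsion (stiffness 5).  Without it, strong
  tension can merge generator pairs; the resulting sliver triangles have
  circumcenter sensitivities ~1/d², which stalls any descent scheme.

## Morphometrics

Shape tensor `S = (1/Z) Σ z_i z_iᵀ` with `z_i` from the polygon's area
centroid (not the generator, which can be off-center) to its vertices.
Elongation = eigenvalue ratio (≥1; note it scales as the squared axis ratio
of the polygon).  Angle deviation = acute angle between the major-axis
eigenvector and the outward radial direction at the centroid, folded to
[0°, 90°] (nematic axes); cells with elongation below 1 + 1e−6 are reported
as undefined and excluded from group means (their count is reported).

Stress: `σ = (1/A) Σ_β (λ/2) t̂_β t̂_βᵀ l_β + K_eff (A/(g_eff A0) − 1) I`,
with radial/circumferential components via the local radial/tangential unit
vectors; junctions shared with exterior cells carry no tension and are
excluded.  Strain: the shape-tensor eigenvalues are rescaled by
`sqrt(A/(π λ_a λ_b))` so they act as the semi-axes of an ellipse of the
cell's area, then divided by the stress-free radius `sqrt(g_eff A0/π)`;
this is the unique reading under which an isotropic cell at `A = g A0` has
principal stretches (1, 1), and it satisfies `ε_a ε_b g A0 = A` identically.

## Fiber orientation and intensity

Local orientation: Gaussian-window gradient structure tensor (default
`σ = 2` px, reflective boundary handling); the fiber axis is the
eigenvector of the smaller eigenvalue (perpendicular to the dominant
gradient), the weight is the tensor energy (trace).  The angle deviation
map folds the axis against the local radial direction into [0, π/2], which
enforces the mirror symmetry of the orientation density.  `k_H` is the
energy-weighted mean of `sin²α`, i.e. the second moment of the empirical
folded density — no density fitting; by default only the top 50 % of
energy pixels enter (background suppression; configurable and reported).
Stacking uses integer-pixel shifts and max-normalization; radial intensity
profiles average pixels in single-pixel-wide concentric zones, distances
normalized by the outermost zone radius.

### Synthetic fiber images

Anti-aliased line segments (default 1000 fibers of 25 px on a 640² canvas)
with midpoints area-uniform in an annulus inside the pattern and angles
relative to the local radial direction drawn from a named density (uniform,
delta, axial von Mises), plus Gaussian noise (σ = 0.05), with the density's
exact `k_H` computed by quadrature.  The canvas/fiber-count defaults keep
the mean fiber spacing above the structure-tensor window: when fibers
overlap much more densely, window averaging collapses per-pixel orientations
onto the local mean axis and biases `k_H` toward its radial limit — the
dominant estimator bias, worth remembering for dense experimental stains.
What the generator does not emulate: curved fibers, intensity gradients,
point-spread blur, and spatially varying density; pipeline validation on it
therefore demonstrates estimator correctness, not robustness to those
real-image effects.

## Phase-diagram protocol

The default sweep covers `g ∈ {0.5, 0.75, 1.0} × rho ∈ {0.4, 0.7, 1.0}` at
`rho_g = 1` with 5 seeds per condition (seeds shared across conditions;
each seed's initialization is computed once and reused).  Group statistics
are means ± s.e.m. over the 5 per-seed group means; comparisons are
descriptive (difference of means against twice the pooled s.e.m.), no
hypothesis tests.

Known limitation: the boundary ring is geometrically special even without
any differential.  Demarcating a circle out of a tiling leaves jagged rim
cells, and the rim tension rounds only their outer edge, so at `g = rho = 1`
boundary cells remain slightly larger (~2 %), more elongated (~0.15–0.2)
and more radially oriented (~39° vs 45°) than interior cells.  Because the
seeded protocol is highly reproducible, the 5-seed s.e.m.s are much smaller
than these structural offsets, so "boundary ≡ interior" in the strict
2×s.e.m. sense does not hold in the null condition; the differences are an
artifact of discrete demarcation, an order of magnitude smaller than the
driven effects, and they do not grow when the differentials are switched
on.

## Micropost traction

`F = (3EI/L³)·x` with `I = πd⁴/64` for a solid circular post; SI units.
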