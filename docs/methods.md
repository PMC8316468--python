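# Methods

`cellsqueeze` simulates deformable, optionally nucleated cells being driven
through microfluidic geometries by a pressure difference, and provides the
measurement and calibration machinery built on top of those simulations:
passage times through a rectangular constriction, threshold pressures in a
tapered funnel, and the inversion of passage-time data for the two
dimensionless cell-line parameters — the nucleus stiffness ratio α and the
karyoplasmic ratio φ.

## Fluid solver

The carrier fluid is evolved with a D3Q19 lattice Boltzmann method with BGK
(single-relaxation-time) collision,

    f_i(x + c_i δt, t + δt) = f_i(x, t) − (1/τ)(f_i − f_i^eq) + h_i δt,

the standard second-order polynomial equilibrium, and Guo's forcing
populations

    h_i = (1 − 1/2τ) w_i [ (c_i − v)/c_s² + (c_i·v)/c_s⁴ c_i ] · g,

paired with the half-force-corrected velocity v = (Σ c_i f_i + δt g/2)/ρ.
The sign convention adds h_i δt so that the first moment of the forcing
injects +(1 − 1/2τ) g of momentum per step; this is the combination that
recovers the Navier–Stokes equations with body force g and is confirmed by
the Poiseuille/rectangular-duct benchmarks in the test suite (flow along
+g, second-order convergence to the duct series solution).

Walls are halfway bounce-back, which conserves mass exactly and places the
no-slip plane half a lattice spacing into the solid; channel masks are
voxelised so that nominal channel faces coincide with those halfway
planes.  Open faces impose a constant density (pressure) by equilibrium
reconstruction, copying the non-equilibrium part from the adjacent
interior node.  This boundary admits a very weak neutral recirculation
mode (observed ≲1 % of an initial perturbation, with exactly zero net
through-flow); it is irrelevant under driven conditions.

Unit mapping: the user supplies δx, the physical kinematic viscosity ν,
density ρ0 and a target relaxation time τ; the time step follows from
ν = c_s²(τ − 1/2) δx²/δt.  All production runs here use τ = 1.0–1.1.  A
low-Mach guard aborts any run whose lattice speed exceeds 0.1 c_s.

## Membranes

Cell membranes are closed triangle meshes (icospheres by subdivision;
20,480 elements per membrane at full production resolution, 1,280 at desk
scale).  The stress-free reference is the undeformed sphere.

In-plane elasticity is the strain-hardening Skalak law
W_s = (G_s/4)[(I1² + 2I1 − 2I2) + C·I2²] per unit reference area.  Each
linear triangle carries a constant surface deformation gradient from its
reference shape; nodal forces are the exact analytic negative gradient of
the assembled energy.  The brute-force energy-differencing oracle in the
test suite verifies this to better than 1e-4 relative error, which is the
ground truth we hold the assembly to.  The area-dilation constant C is not
a measured quantity here; the default C = 50 puts the membrane in the
nearly area-incompressible regime, and every quantitative check either
does not depend on C or states it explicitly.  A 12-control-vertex Loop
subdivision patch query is available on the mesh (regular patches on
valence-6 neighbourhoods; the 12 valence-5 icosphere vertices flag their
60 incident elements as irregular) for smooth-surface evaluation.

Bending follows Helfrich, W_b = (E_b/2)∮(2κ − c0)² dS with E_b = 1e-18 J
and c0 = 0 by default, discretised with the cotangent Laplace–Beltrami
mean curvature and barycentric (one-third) vertex areas.  Barycentric
rather than mixed-Voronoi areas keep the discrete energy branch-free, so
its gradient — including the cotangent and area variations — can be
assembled analytically; the finite-difference oracle verifies it to
~1e-3.  On icospheres the discrete operator carries mesh noise
concentrated at the twelve valence-5 vertices: the sphere's bending energy
converges to the scale-invariant 8πE_b (within 3 % at level 4), but
pointwise nodal bending forces on a discrete sphere do not vanish — they
are balanced noise that neither translates nor spins the cell, and are
negligible against the Skalak forces at the moduli used here.

## Immersed-boundary coupling

Velocity interpolation and force spreading use the cosine-product
regularised delta with four-point support per axis.  Its discrete lattice
sum is exactly one for any membrane position (so spreading conserves the
total membrane force to round-off), but its discrete first moment is not
zero: interpolating a linear field carries an O(0.02 δx) error per unit
gradient.  Only the continuous integral of the cosine kernel has a
vanishing first moment; the discrete moment condition would require the
piecewise-algebraic four-point kernel instead.  We keep the cosine form —
it is the kernel this model family is defined with — and the test suite
pins the defect's magnitude.

Near walls the part of a vertex's support that falls on solid nodes is
dropped and the remaining weights renormalised, preserving the partition
of unity; this keeps interpolation and spreading consistent for cells
squeezing through gaps comparable to the kernel width.  A vertex pressed
so hard into a wall that no fluid node remains in its support receives
zero weights (no velocity, no spread force) and a warning; the membrane
tension retracts it.  The Lagrangian update is forward Euler; a
diagnostic warns if any vertex moves more than δx/2 per step.

## Cell models

* single-membrane: one Skalak+Helfrich membrane (G_s the only stiffness).
* nucleated: outer membrane (G_s = 5e-5 N/m, the literature-scale plasma
  membrane tension) plus a nucleus membrane with G_s,nuc = α·G_s at radius
  r·φ^{1/3}, concentric at start.
* spring-augmented: the nucleated cell plus a Hookean cyto- and
  nucleoskeleton.  One spring per outer element (centroid projected along
  the inward normal onto the nucleus) and one per nucleus element
  (projected to the opposing side); F = k·dL with k = E·A/L0, a common
  Young's modulus E (950 Pa reproduces the constriction data in the source
  experiments), A the source element's reference area.

When the membranes turn locally concave (cell entering a constriction),
straight springs can exit the cell.  Every N_adapt steps (default 100)
each spring re-anchors by casting a ray from its source centroid along the
inward element normal and connecting to the first element hit — nucleus or
outer membrane.  Rest lengths are reassigned to preserve the spring's
instantaneous tension (L0 ← L·L0_old/L_old), avoiding force jumps at
reconnection; a tension-reset alternative (L0 ← L) is available.  The
element normal (not a vertex-averaged normal) defines the ray, and
nucleoskeleton springs adapt by the same rule.  A winding-number oracle in
the tests confirms that after adaptation no sampled spring point lies
outside the membrane in a squeezed-dumbbell configuration that defeats the
static network.

## Multi-resolution pressure coupling

Only 75 μm of the constriction device (25 μm constriction + 50 μm of
inlet/outlet) is simulated in 3D; the remaining 950 μm of main channel and
25 μm of constriction are hydraulic resistances from Boussinesq's
rectangular-duct series (evaluated as tanh(β_n l/2) terms, truncated at
120 terms, tail < 1e-10; either assignment of the section sides to (h, l)
yields the same flow rate, verified against a finite-difference Poisson
oracle to 0.1 %).  Each step, the flow rate measured on a plane in the 3D
inlet region (smoothed by an exponential moving average, α = 0.02) sets
the lumped drops, and a PI controller tracks the resulting target inlet
pressure.  Gains come from step-response measurements on the coupled
device: the 3D domain responds over its viscous time (hundreds of steps at
desk scale) and the loop gain is R_lumped/R_3d ≈ 3, so K_p = 1e-3 per step
with K_i = 1e-6 (and anti-windup at the pressure clamps) is well damped;
the closed-loop surrogate test shows settling within 1e4 steps,
no sustained oscillation, and the physically expected transient (pressure
across the cell rises as the cell's resistance cuts the flow).  Driving
pressures ramp linearly over the first ~1.5–3e3 steps, with cells held as
rigid obstacles until the ramp ends, so that event times are measured
under developed-flow conditions.

## Experiments

Passage runs drive one cell through the constriction device
(20×15 μm main channel, 6×15 μm constriction) under the 0.9 psi
reservoir-to-reservoir difference with the lumped segments attached.
Event planes: entry runs from first contact of the leading vertex with the
constriction entrance plane until the trailing vertex crosses it; transit
until the leading vertex crosses the exit plane; τ_p is their sum.  Cells
elongated beyond the constriction length can cross the exit before
finishing entry; both events are awaited.  A stall detector (centroid
speed below 1e-3 of the carrier speed over 5e3 steps) returns a stuck
verdict.

Threshold runs place a nucleated cell in the funnel taper, as close to the
pore as it fits undeformed, and determine the minimum quasi-static ΔP to
pass the waist, by bisection between a stuck and a passing pressure
(`run_threshold`) or by staircase loading — raising ΔP one rung
(default 15 Pa) per dwell window until the trailing vertex clears the
waist (`run_threshold_ramp`).  The staircase mirrors the gradual loading
protocol of the physical experiment at one run per pore and is used for
pore-size sweeps; bisection refines a single pore to a requested bracket.
The funnel taper half-angle (10°) and depth (15 μm) are package defaults,
configurable, chosen to reproduce the published device silhouette.

Calibration: for a cell size with target passage time τ*, φ*(α) is found
by monotone interpolation of log τ_p against φ (passage time grows
exponentially in φ), optionally confirmed by one extra simulation.  Loci
from ≥2 sizes are intersected by minimising the sum over sizes of squared
normalised point-to-locus distances on the (α, φ) plane (coarse grid scan
plus Nelder–Mead polish); non-overlapping loci produce the nearest
approach plus a warning.

## Desk-scale study conditions

Full production resolution (δx = 0.15 μm, level-5 meshes) is far beyond a
single-CPU test budget, so all behavioral checks run a geometrically
faithful desk-scale configuration: δx = 0.75 μm (8 nodes across the 6 μm
gap, 40 at production resolution), level-3 meshes (1,280 elements),
physical fluid properties (ν = 7.8e-7 m²/s, ρ = 1060 kg/m³), and τ = 1.0–1.1.
At this resolution the four-point kernel support (3 μm) is half the
constriction gap, so lubrication films are under-resolved and membranes
leak slightly; absolute passage times and threshold pressures are
therefore not expected to match production-resolution values, and the
desk-scale suite asserts orderings and ratios, not absolutes.  To keep the
nucleus rate-limiting despite the smeared hydrodynamics, the passage
sweeps use the larger cells of the studied range (r = 7 μm for the α and φ
sweeps) and a reduced driving pressure of 2000 Pa, under which entry is
elasticity-dominated; the radius sweep runs at the same conditions.
Threshold sweeps use a 12 μm cell (it must clear the 15 μm funnel depth
undeformed at initialisation) with the standard pore set.  These choices
are fixed as the package's desk-scale benchmark; the full-scale
configuration remains the default of the geometry and unit-mapping layers.

What the desk-scale suite does show: entry-dominated passage, passage time
increasing in α, φ and cell radius, threshold pressure decreasing in pore
width, pressure-budget closure of the multi-resolution coupling, and
bit-identical trajectories for identical configurations.  What it cannot
show: quantitative agreement with experiments at production resolution,
resolved lubrication layers, or membrane-viscosity effects (not modelled).

## Numerical guards and degenerate inputs

Non-finite populations or non-positive densities raise immediately with
the step index; the Mach guard aborts at |v| > 0.1 c_s; degenerate
reference elements are rejected at mesh construction and degenerate
current elements are reported with their ids; φ outside (0,1), τ ≤ 1/2 and
non-positive dimensions are rejected on input.  Spring rays that miss all
elements (open meshes, extreme numerics) keep their previous anchor and
warn rather than fail.
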