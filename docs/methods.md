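# Methods

`avatum` simulates the growth of an avascular tumor spheroid limited by
the diffusion and consumption of two nutrients, glucose and oxygen, in
two culture settings: a static unlimited medium and a perfused
microfluidic trap. This note records the model, its assumptions, the
numerical choices and their rationale, and what the shipped defaults do
and do not represent.

## Growth model

The spheroid of radius `R` is partitioned into three concentric regions
by the local nutrient concentrations relative to their critical values
`C_crit` (strict comparison; at exact equality a point counts as the
more viable class):

| zone          | condition                      | division | uptake factor |
|---------------|--------------------------------|----------|---------------|
| proliferative | both nutrients >= critical     | maximal  | 1             |
| quiescent     | exactly one below critical     | none     | 1/2           |
| necrotic      | both below critical            | dead     | 0             |

Uptake follows Michaelis–Menten kinetics `f * Vmax * C / (Km + C)` with
the zone factor `f` above. The tumor volume obeys

    dV/dt = A (V - Vq) - Ap (V - Vn) - An Vn

with `Vq` and `Vn` the volumes enclosed by the quiescent and necrotic
boundaries. `Vq` is *cumulative* (quiescent shell plus necrotic core),
so proliferation `A (V - Vq)` acts only on the proliferative shell while
apoptosis `Ap (V - Vn)` acts on all viable cells — the reading
consistent with apoptosis operating everywhere except the necrotic
core. `A = ln 2 / 21 h = 3.3e-2 1/h` comes from the EMT6/Ro exponential
doubling time; `Ap = 1.2153e-9 1/s` and `An = 2e-6 1/s` are the
apoptosis and necrosis loss constants. All parameter defaults (the
EMT6/Ro mouse mammary carcinoma profile, water at 37 °C) ship in
`data/emt6ro.toml`; concentrations use 1 mM = 1 mol/m^3.

Growth is *quasi-steady*: nutrient diffusion equilibrates in minutes
while the spheroid doubles in about a day, so at each growth step the
steady concentration problem is solved for the current geometry, the
zone volumes are integrated, and the volume is advanced one
forward-Euler step of `dt = 20 h` (configurable; a step-halving
comparison ships as a test). The Euler update uses the rate at the step
start. The volume is floored at one cell (8.1 um radius), flagging
extinction rather than going negative. Volumes are always reported for
the full sphere.

## Static-medium solver (`radial_sim`)

In an unlimited static medium the surface concentration stays at the
bulk value and the problem is spherically symmetric:

    (1/r^2) d/dr ( r^2 dC/dr ) = f(r) Vmax C / (Km + C) / D_tissue,
    dC/dr = 0 at r = 0,   C = C_bulk at r = R.

Discretization is a vertex-centred finite-volume scheme on >= 200
radial nodes (default 256), exactly conservative with respect to its
own quadrature; the Michaelis–Menten sink is linearized with a lagged
denominator (`Vmax C_new / (Km + C_old)`), which keeps the tridiagonal
system an M-matrix — positivity is preserved — and is Picard-iterated
to 1e-12. After a first convergence, nodes are clustered geometrically
around the detected boundaries and the solve repeats once.

Because the zones are defined by the very concentrations they control,
the solver iterates {solve; reclassify} to a fixed point of `(Rq, Rn)`:

- The zone factor is **partial-volume weighted** per control volume
  (the r^2-measure fraction of each cell in each zone). A nodewise step
  factor makes the solve->reclassify map discontinuous whenever a
  boundary crosses a node, and the discrete fixed point can then fail
  to exist.
- The primary iteration relaxes boundary moves by 0.5, halving the
  relaxation whenever a boundary's move changes sign (onset of a zone
  makes the map oscillatory) and recovering it otherwise; cap 100
  sweeps, termination when both boundaries move < 1e-6 R.
- Once a necrotic core appears the crossing-radius formulation is
  ill-posed: no nutrient is consumed in the core, so the binding
  (less-deficient) nutrient's profile is *flat* there and its crossing
  radius is infinitely sensitive. The well-posed condition is that the
  core plateau sits exactly at the critical concentration, and `Rn` is
  found by Brent root-finding on (centre concentration - C_crit),
  which is monotone in `Rn`; `Rq` is likewise pinned by Brent on
  (outermost crossing - Rq). The two one-dimensional solves alternate
  until neither boundary moves.

A converged profile must satisfy a discrete residual below 1e-3 (the
solve itself reaches machine precision; the check guards the
free-boundary iteration) and non-negative concentrations.

Zone boundaries are located by inverse linear interpolation of the
monotone profiles between nodes.

## Perfused-chip solver (`chip`)

The chip holds one spheroid per trap in a perfused channel; the meshed
domain is half of a single-trap unit cell (the mid-plane through the
tumor centre and the outer side face are both symmetry planes — the
chip carries a row of identical traps). Two trap variants share length,
width, cross-section area and height by construction: a **U-shaped
barrier** standing on the channel floor with its opening facing
upstream, and a **microwell** recessed into the floor (depth = barrier
height). The tumor is a rigid, stationary, full sphere resting tangent
to the trap floor; intratumoral convection is neglected (interior
velocity identically zero).

The published trap designs this follows state their dimensions only on
a figure, so the shipped geometry (`data/fig2_default.toml`) is an
explicit, documented reconstruction at the same scale — channel
3000 x 1200 x 800 um, trap 700 x 700 x 250 um, wall 50 um — and every
dimension can be overridden. Absolute chip-scale volumes therefore
cannot be pinned against published curves; the package asserts the
*orderings* (flow-rate and trap-geometry effects) and the shear
envelope instead.

**Flow.** Steady incompressible flow on a marker-and-cell staggered
rectilinear grid (velocities on faces, pressure in cells): discrete
divergence is exact and the saddle system symmetric. At chip scale the
Reynolds number is at most O(1), so the convective term is dropped by
default (Stokes); `scheme="navier_stokes"` restores the steady
Navier–Stokes equations via Picard (Oseen) iteration with first-order
streamwise upwinding, and a test verifies the correction is < 1% at
the studied rates. Boundary conditions: uniform-flux inlet,
zero-gradient outflow with pressure datum 0, no-slip on floor, ceiling,
trap walls and tumor surface (stair-step voxels with half-cell wall
distances), free-slip symmetry on the side faces. The linear system is
solved by eliminating the SPD velocity blocks with exact sparse LU and
running conjugate gradients on the pressure Schur complement with a
(1/mu)-scaled mass-matrix preconditioner; residuals reach ~1e-10,
comfortably below the 1e-6 criterion, and mass balance holds to
machine precision. Stokes flow is linear in the inlet rate, so a
solved field can be rescaled exactly (`FlowField.scaled`).

**Transport.** A single-domain conservative finite-volume solve with
piecewise coefficients: harmonic-mean face diffusivities (medium
outside, tissue inside the tumor; flux continuity across the surface
follows from conservation), first-order upwind advection outside the
tumor, Dirichlet feed concentration at the inlet (advective plus
diffusive), impermeable walls, advective-only outflow. The
Michaelis–Menten sink acts in tumor voxels with the zone factor.

The 3D zone fixed point reuses two ideas from the radial solver plus
one of its own:

- the lagged-denominator linearization;
- relaxation (0.5) of the per-voxel factor toward its reclassified
  target, with the same halve-on-oscillation / recover-on-contraction
  adaptation;
- a **smoothed deficiency indicator**: a voxel whose concentration lies
  within +-2.5% of `C_crit` gets a fractional deficiency (linear ramp),
  i.e. a sub-voxel interface position. A binary indicator flips
  indefinitely on the flat core plateau; the ramp makes the map
  continuous, and the converged fractional indicators also provide
  sub-voxel-sharp zone volumes. Zone volumes are reported as the
  indicator-weighted voxel fractions applied to the *analytic* sphere
  volume, so voxelization does not bias the growth law.

Each outer sweep changes only tumor-voxel diagonal entries, so the
fluid block is factorized once per call and eliminated; a sweep then
costs one small dense Schur solve on the tumor voxels. The initial
factor field comes from the spherically symmetric solution at the same
radius. Convergence requires concentration moves < 1e-6 of the feed and
factor moves < 1e-3; the final nonlinear residual must be < 1e-3.

**Wall shear stress.** For every fluid voxel face-adjacent to the
tumor, the tangential part of the cell-centre velocity (with respect
to the radius from the tumor centre) is sampled at that voxel and at
one further voxel outward along the same radial ray, and the surface
velocity gradient is obtained from a quadratic-through-zero fit to the
two samples. The two-point extrapolation cancels the leading curvature
error of a plain first difference (the tangential velocity around a
no-slip sphere grows sublinearly with wall distance) and regularizes
the stair-step voxelization; the first sample distance is clamped
below at half the local cell size because the discrete no-slip surface
is the voxel face. On an isolated sphere in uniform Stokes flow the
estimate reproduces the classical `(3/2) mu U / a` peak traction to
~1%, and doubling the default mesh changes it by < 10%. Stress is
reported in dyn/cm^2 (1 Pa = 10 dyn/cm^2). The published safe-culture
envelope discussed with these traps is stated in dyn/cm^2 (a stress),
and that is what is computed.

**Growth coupling.** Per 20 h step: rebuild the voxelization for the
current radius, solve the flow once for that geometry, solve transport,
integrate the zone volumes, advance the volume ODE. The growth law sees
only the zone volumes, not their spatial arrangement, so the asymmetric
chip fields enter purely through `Vq` and `Vn`.

## Workbench

All inputs are TOML; an empty file yields the complete default profile.
Values may carry explicit unit strings ("0.8 mM"); bare numbers take
the key's declared unit. Validation reports every violation at once,
and load -> dump -> load is idempotent. The model contains no random
number generation anywhere, so no seeds are exposed and every scenario,
batch and CSV is bit-reproducible.

`paper_scenarios()` materializes the canonical experiment set: the
550 h nutrient-concentration sweep (oxygen 0.22–0.34 mM x glucose
0.6–1.0 mM, R0 = 24.286 um; 4 x 5 grid by default), the initial-radius
sweep (8.1–48.6 um at 0.6 mM glucose / 0.24 mM oxygen), the 0.8/0.28 mM
baseline, the 300 h flow-rate sweep (0.5/5/50 uL/min, U-barrier) and
the U-barrier vs microwell comparison at 5 uL/min.

## Problem sizes and horizons

- Radial grid: 256 nodes (tests of grid convergence use 256 vs 512;
  the long dormancy runs use 128, which reproduces the boundaries to
  the micrometre).
- Chip mesh: 30 um fine-region cells by default (about 12k cells for
  the default geometry), coarsening 3x away from the trap; the
  refinement-stability test doubles this on a compact single-trap
  channel.
- Horizons: 550 h for the static concentration sweep, 300 h for the
  perfused runs (both as published). The initial-radius-independence
  claim is about the *final, dormant* volume; under the shipped
  kinetics the trajectories from 8.1–48.6 um merge only once growth
  has effectively stopped, so that scenario runs to 2400 h, where the
  growth per step is below 0.5% and the volume spread is ~2%.

## Known limitations

- The stair-step voxel tumor surface limits the pointwise accuracy of
  the shear field; only the maximum (with the corrections above) is
  validated. Early growth steps resolve the spheroid with only a few
  voxels; during those steps the tumor is entirely proliferative, where
  the growth law is exact regardless of resolution.
- First-order upwind advection adds numerical diffusion outside the
  tumor; the solute-balance audit (1%) bounds its effect on the
  quantities that drive growth.
- The quiescent->proliferative transition is treated as instantaneous
  and reversible; no cell-cycle, single-cell or pH effects (and no
  inhibitor chemistry) are modelled.
- The trapped tumor is rigid and cannot deform, migrate or escape;
  pulsatile flow and multi-trap interactions are out of scope.
- The smoothed deficiency band (2.5% of C_crit) sets the sharpness of
  the 3D zone boundaries; its effect is bounded by the
  refinement-stability test.
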