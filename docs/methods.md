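# Methods

`zconstrict` is a coarse-grained particle simulator of FtsZ-driven
bacterial cell constriction.  It couples four components — a bead-sheet
membrane, a turgor-pressurized spring-grid cell wall, FtsZ filaments in
two mechanical representations, and FtsZ–membrane linkers in three
variants — and integrates them with an adaptive-step overdamped
Langevin scheme.  This note records the model, its assumptions, the
numerical conventions, and the limits of what the accelerated test
systems demonstrate.

## Unit system

Internal units are nm (length), pN (force) and s (time); energies are
pN·nm (1 pN·nm = 10⁻²¹ J).  Literature constants quoted in SI are
converted once at the configuration boundary: filament bending
stiffness k_θ = 3.8·10⁻¹⁸ J → 3800 pN·nm, lateral well depth
ε = 5·10⁻¹⁹ J → 500 pN·nm, damping γ = 10⁻⁷ N·s/m → 10⁻⁴ pN·s/nm, and
turgor P = 1 atm → 0.101325 pN/nm².

## Membrane

The membrane is a single layer of beads on a cylinder (160 nm wide,
250 nm radius by default; long axis = x).  Beads are laid on rings with
8-nm axial spacing, each ring holding `round(2πR/8)` beads, alternate
rings rotated by half an angular spacing so the sheet triangulates; the
axial direction is periodic (minimum-image convention with period equal
to the width, which realises the edge-image boundary).

Mechanics: any two membrane beads closer than d_mb = 8 nm repel with
k_pair(d_mb − d)², and *paired* beads further than d_pair = 16 nm
attract with k_pair(d − d_pair)² (k_pair = 1 pN/nm²).  The pair list is
rebuilt from proximity every 10⁴ steps (2·10³ at mini scale); a
candidate pair is dropped only when the outward tangent-plane projection
shows it crossed by more than one shorter pair, so bead neighbourhoods
can exchange and the sheet flows.  The precise lattice, the geometric
definition of "crossed", and the quad-derivation rule are conventions
of this implementation, not published facts.

Bending stiffness: every four beads sharing five pairs form a quad
whose diagonals are pulled together.  The quad energy is k_mb·s², with
s the distance between the two diagonals along their common normal, and
forces are its exact analytic gradient (per-bead magnitude ≈ k_mb·|s|;
zero net force and torque per quad).  Only four-bead sets whose
diagonals genuinely cross in the tangent projection are kept.
Calibrating k_mb by matching the mesh bending energy of the built
cylinder to the continuum value k_m_exp·πL/R (k_m_exp = 2·10⁻¹⁹ J)
gives ≈ 4.4 pN/nm on this mesh; the published 8 pN/nm corresponds to a
different (unstated) quad convention, so the default remains 8 pN/nm
and the calibration documents the mesh dependence.

## Filament sliding model

Filaments are polar bead chains (one bead per monomer, minus end
first): backbone springs (l_z = 4.4 nm, k_z = 500 pN/nm), harmonic
angle bending k_θ(θ−θ₀)²/2 at interior beads (θ₀ = 0), a 12-6
Lennard-Jones interaction between beads of *different* filaments
(ε = 500 pN·nm, zero-potential distance ρ = 6.5 nm, cutoff 3ρ — the
force there is <0.3 % of the well force; no shift), and an optional
ring separator: beads of different rings repel below d_s = 20 nm with
k_s(d_s − d), k_s = 50 pN/nm.

Rings are built to close: filament bead counts are drawn uniformly
(20–60 full scale, 10–20 mini) until the summed arc exceeds
`overlap_factor` (default 1.3) times the circumference, then placed
head-to-tail with every junction overlap at least two subunits and the
remaining excess distributed randomly.  Overlapping neighbours are
staggered radially by 2^{1/6}ρ so overlaps start at the
lateral-potential minimum.  Polarity (treadmilling direction) is a
random sign per filament and only selects which geometric end is the
minus end.

Depolymerization removes minus-end beads; treadmilling adds a plus-end
bead along the terminal bond direction and removes a minus-end bead per
event.  Events fire on a deterministic simulated-time clock at
intervals 1/rate (a Poisson clock is available as a config switch);
filaments below two beads are removed.  An optional per-pair ε scaling
(s_par, s_anti) implements the parallel/antiparallel interaction
variants.

The lateral free-energy profile of two parallel chains vs registry
shift is computed as a direct lattice sum.  The profile superposes a
monotone "zipper" tilt (overlap keeps growing) on a registry
corrugation; the avidity barrier reported by `overlap_barrier` is the
detrended corrugation amplitude, which grows with the number of lateral
bonds.

## Filament bending model

Each monomer is a cube of edge l_z; adjacent cubes share a face, so the
filament is a chain of four-bead cross-sections.  Cross-section edges
and two junction edge-midpoint springs carry (k_z, l_z); per junction,
two C-face springs (beads 1–5, 2–6) and two N-face springs (3–7, 4–8)
carry constant k_b and relaxed lengths l_C, l_N.  In the straight
(GTP) state l_C = l_N = l_0, the live distance between the
cross-section centres (never frozen; its gradient is included in the
forces).  After hydrolysis l_C = l_0 + Δl_0 and l_N = l_0 − Δl_0 with
Δl_0 = l_z·sin(θ_b/2); reverse bending swaps the two.  k_b follows from
equating the four-spring energy 4·(k_b Δl_0²/2) to the harmonic bending
energy k_θθ_b²/2.  Anti-twist: on every cube face a force k_z·Δl (half
per bead) equalizes the two diagonals.  All filaments switch from
straight to their bent state at t = 0.

The preferred angle maps to the diameter of the circle a free filament
closes, θ_b = 360·l_z/(πd) degrees: 250 nm ↔ 2°, 50 nm ↔ 10°.  A free
filament relaxed without partners reaches the corresponding arc
curvature within 5 % (verified by test).

Treadmilling of cubes continues the filament's current arc: the new
cross-section is the terminal one rotated by the turn between the last
two centre-to-centre segments (plain translation would walk the
filament off its circle).  The division-plane constraint applies
k_dp·d (k_dp = 20 pN/nm, d = long-axis projection) to both ends of the
radial cube edges (1-4, 2-3 per cross-section) in rigid-linker
scenarios.  A `tilt_deg` build option rotates the cube frame about the
filament axis, tipping the bending plane out of the division plane; it
seeds the rolling instability deterministically for the
linker-comparison tests.

## Linkers

Flexible: two springs (k_lk = 20 pN/nm, 8 nm each) joined at a free
FtsA/ZipA bead (no angular energy); attached every 4 monomers to the
nearest unclaimed membrane bead.  Circumferential: additionally, the
long-axis separation of adjacent linkers' membrane beads is penalized
with k_c = 20 pN/nm (the axial projection is used; penalizing the full
out-of-circumferential component would add a spurious radial force on a
curved surface).  Rigid: a single 16-nm spring plus k_r = 3 pN/nm on
the ends' separation perpendicular to the radial direction (radial =
from the long axis through the membrane bead); the gradient of the
direction itself is included so forces are exact.  Cube filaments
anchor at the cube centre (forces distributed over its eight beads by
the chain rule).  On remodeling, linkers of removed monomers are
deleted and a new plus-end linker attaches once the monomer count since
the last anchor reaches the spacing.  Joint beads are phantoms except
for their two springs (no volume exclusion).

## Cell wall, turgor, coupling, growth

The wall is a grid of bead hoops (11 hoops of 104 beads at full scale;
hoop spacing 16 nm, radius 265 nm, 15 nm outside the membrane).
Circumferential glycan springs (k_g = 100 pN/nm) carry per-spring
dynamic relaxed lengths; axial peptide springs carry (k_p = 10 pN/nm,
l_p = 16 nm).  The initial relaxed length l_g = l_ext − (P·r_g/k_g)·l_p
makes turgor stretch every glycan spring to the as-built bead spacing
(11.70 nm from the printed constants; the builder uses the actual chord,
which differs from 16 nm only by bead-count rounding, so the built
cylinder is the turgor equilibrium).  The two outermost hoops are
translational images: the last hoop carries no glycan springs of its
own, and the two hoops' forces are summed and applied to both, keeping
them congruent.

Turgor is the gradient of the enclosed volume.  The volume of the
triangulated lateral surface is computed by the divergence theorem with
the field F = (0, y, z)/2: exact for the tube (the open ends contribute
zero flux) and axially translation-invariant, so edge hoops feel
interior-like gradients.  An apex-at-centroid tetrahedron sum was
evaluated first and rejected: its open boundary fans exert a spurious
~30-pN inward force on the edge hoops and underestimate the enclosed
volume by one third.  The per-bead outward force on the built cylinder
is P·(16×16 nm²) ≈ 25.9 pN, balancing the glycan pre-tension to <0.02 pN.

Membrane–wall coupling: the squeeze force k_w·Δd² (k_w = 1.6 pN/nm²)
restores each membrane bead to 15 nm from the local wall surface — the
tangent plane at the nearest wall bead, with the normal built from its
hoop/axial neighbour differences.  Forces are the exact gradient of the
implied energy (k_w|Δd|³/3), so the reaction lands on the nearest wall
bead and its four neighbours with the weights the chain rule dictates.
Growth: every scheduling interval, each membrane bead whose gap exceeds
15 nm + `gap_trigger` moves its nearest wall bead inward (radially) by
min(0.05 nm, ν_w·Δt) and shortens that bead's two glycan springs by
πΔd_w/N_b; relaxed lengths only ever shorten (floor 10⁻³ nm).

## Dynamics

With inertia neglected the displacement is dX = F·dt/γ.  Per step,
every bead moves d_max·F_i/F_max along its force (d_max = 0.01 nm at
full scale) and the time step is dt = γ·d_max/F_max, capped at 10⁻⁶ s
against the zero-force singularity.  Thermal forces are k_rand·N(0,1)
per component (k_rand = 5 pN, the midpoint of the explored 1–10 pN
range), with Gaussians from the Box–Muller transform, refreshed every
step and deliberately not rescaled by √dt — the temperature is a force
scale, not a physical temperature.  Volume exclusion: FtsZ–membrane
bead pairs below 8 nm repel with k = 200 pN/nm; in the bending model,
cube centres of different filaments below 6.5 nm repel with 1 nN/nm
applied to all eight beads of both cubes; the sliding model's
Lennard-Jones term provides its own exclusion.

Neighbour lists (Lennard-Jones, separator, exclusion, membrane
repulsion, nearest-wall map) are rebuilt every `neighbor_interval`
steps with a skin chosen so the displacement cap cannot invalidate them
between rebuilds (2·interval·d_max ≤ skin).  Remodeling events fire
when simulated time crosses the event clock; one master seed feeds
separate build/thermal/remodeling streams, so trajectories are
bit-reproducible.  With thermal forces off, the integrator is a capped
steepest descent and the total potential energy is non-increasing
(verified by test).

## The mini scale

Published production runs are 10⁹–10¹⁰ steps; the test systems use a
smaller, accelerated configuration chosen once during fixture design:
a 60-nm-radius, 64-nm-wide membrane (75-nm wall, 44-nm filament ring),
10–20-bead filaments, displacement cap 0.1 nm, growth scheduling every
125 steps, a 2-nm growth trigger under thermal forces (position noise
scales with the cap; with deterministic runs the published 0.5-nm
trigger is used), and remodeling/growth clocks sped up by a common
factor (2·10³ on the preset rates; the qualitative tests pass explicit
accelerated rates) so that rate ratios, not absolute rates, carry over.
Elastic-driven phenomena (filament bending, rolling, reverse-bending
constriction) are probed deterministically (k_rand = 0) because the
capped integrator then spends its step budget on the driving forces.

What the mini systems do and do not show.  They reproduce: lateral
attraction collapsing rings into bundles and separators preventing it;
the rolling instability of bent filaments on flexible linkers and its
suppression by rigid linkers with the division-plane constraint;
monotonic wall constriction under rigid-linker bending at high filament
curvature; the reverse-bending advantage at low curvature (traditional
bending triggers no inward wall growth where reverse bending does); and
single-filament constriction.  They do *not* reach the sliding model's
steady state: desk-scale windows are dominated by the initial elastic
relaxation of the overlapping-ring initial condition, which constricts
the no-remodeling control at least as fast as a depolymerizing run and
breaks ring coverage before the first depolymerization event can fire.
The stall-versus-depolymerization rate contrast and the critical-rate
ring-break ordering are therefore *not* reproduced at this scale; the
corresponding tests state the expected steady-state property and fail,
documenting the gap rather than masking it.  For the bending
comparisons the cumulative glycan shortening (irreversible by
construction) is the constriction readout; instantaneous radii
oscillate elastically.

In the mini rigid-linker constriction test the filament's preferred
diameter is set to one tenth of the membrane diameter — the ratio of
the published working point — rather than its absolute angle, since
the curvature *difference* drives the constriction force.

## Numerical choices and degenerate inputs

Distances are floored at 10⁻³ nm (coincident beads are pushed apart
along a seeded random direction and logged); the Lennard-Jones distance
is clamped at 0.3ρ to bound the r⁻¹² blow-up.  Collinear quads are
skipped.  Removed beads are parked far from the domain and excluded
from integration, neighbour search and output rather than compacting
the arrays (index stability).  All force terms are exact analytic
gradients of their energies (verified against central differences at
10⁻⁵ relative tolerance over randomized configurations), with three
documented exceptions that are constraints rather than potentials: the
edge-hoop force tie, the growth rule, and the remodeling moves.
Ring integrity is coverage of the ring circle by the filaments'
angular spans (projected on the ring's best-fit plane); simulation
metrics treat gaps narrower than the lateral-interaction cutoff as
mechanically connected, since tension is still transmitted across them.

## Known limitations

Membrane topology is fixed (no fusion/fission at deep constriction);
hydrolysis is a global t = 0 switch, not per-interface kinetics; the
thermal force has no physical temperature, so barrier-crossing rates
are not calibrated; the sliding model's steady-state behaviour is out
of desk-scale reach (above); linker density (1 per 4 monomers) and the
ring-layout conventions are choices the source material does not
constrain.
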