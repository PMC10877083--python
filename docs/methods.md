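# Methods

This note documents the physical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Energy model

**Geometry and units.** Lengths are nm, energies kBT (T = 300 K unless a
nanoparticle says otherwise), charges elementary, concentrations mol/L,
times s.  Unit conversions happen only inside `cg_model` (SI constants) and
`rate_param` (the m³ → L factor of 1000 in the adsorption rate).

**Bead surface separation.** Each bead's `ssd` is the exact sphere
convention `|bead − NP centre| − R_NP`.  For the distance sweep the molecule
sits above the particle's north pole, translated so its lowest bead is at
nominal separation `d` along the polar axis; off-axis beads automatically
pick up the curvature correction.  For R_NP ≳ 50 nm this converges to the
planar-slab geometry in which the PMF tables are defined; a single bead
reproduces its PMF identically.

**PMF tables.** Linear interpolation, exact at nodes.  Below the first node
the first segment's slope is continued and capped at +50 kBT (hard wall);
above the last node the energy is exactly 0.  Tables must be strictly
increasing in `ssd`, finite, tail-anchored within 0.5 kBT of zero, and carry
at least 3 samples (generated tables carry ~300).

**Electrostatics.** The published model names a screened Coulomb potential
without a formula.  We use the linearised Poisson–Boltzmann closure for a
point charge near a uniformly charged sphere held at the zeta potential:
`U = q e ζ (R/(R+h)) exp(−h/λ_D)` with h the bead's ssd.  The default Debye
length 0.78 nm corresponds to 150 mM NaCl near room temperature.  At
ζ = −5 mV this term is small (|U| ≤ 0.2 kBT per unit charge), so the choice
of closure is not load-bearing for the benchmark system.

**Hamaker core term.** Classical two-sphere Hamaker expression with the bead
radius as the second sphere (the sphere–point limit as the bead shrinks).
The constant is configurable and defaults to off (0 J): no aluminium Hamaker
constant is established for this system, and beads flagged `small` (the
glucose bead) skip the term regardless.

**Distance averaging.** `E_ads` per orientation is the Boltzmann-weighted
*mean energy* ∫U e^(−U) dd / ∫e^(−U) dd — not the −ln Z free energy — over a
window from the PMF wall to 1.5 nm in 0.005 nm steps, by trapezoidal
quadrature with a min-energy shift for overflow safety.  The mean-energy
reading follows the quoted weighting-factor construction; a −ln Z free
energy would differ by an entropic width term of order ln(window/width),
i.e. a few kBT, and would not change any ranking used here.

**Orientations.** The canonical frame puts the smallest inertia moment on z
and the second smallest on y, then flips 180° about x and/or z until the
dipole components along z and y are non-negative.  Single beads (and
molecules with a vanishing dipole) have no unique frame; they fall back to
the solver's eigenbasis, with a warning for single beads.  Orientation
(φ, θ) applies a rotation of −φ about z followed by 180° − θ about y, so
(0°, 180°) is the identity.  The default grid spacing is 5° in both angles.
The polar rows θ = 0°, 180° would get zero sin-weight on any grid; they
receive their half-cell midpoint weight sin(spacing/2) instead so coarse
grids do not silently drop polar orientations.

## Rate parameterisation

**Footprint.** Beads (as discs of their bead radius, sampled as 64-gons,
0.16% area error) are projected radially onto the sphere and mapped
gnomonically to the tangent plane at the sub-molecular point; since the
gnomonic projection maps great circles to straight lines, the planar convex
hull *is* the spherical hull.  The planar polygon area is used when the
footprint subtends ≤ 10° of arc (exact to first order in that regime; all
benchmark species are far below it) and the spherical-excess polygon area
beyond, so 2 nm particles remain valid.

**Effective radius.** Inverts the shadow construction: a sphere of radius
R_i resting on the particle subtends a tangent cone of half-angle α with
sin α = R_i/(R_NP+R_i) and casts a cap of area 2πR²_NP(1−cos α).  Footprints
of a hemisphere or more have no finite generating sphere and raise an error.
In the planar limit R_i → √(A/π).

**Rates.** `ka` is the two-sphere collision rate (pair diffusion
coefficient D = kBT/(6πη)(1/R_NP + 1/R_i), η = 8.9×10⁻⁴ Pa·s) normalised by
the number of binding sites N_sites = 4πR²_NP/A_i, which is kept real-valued
— rates, not lattice sites, drive the simulation.  `kd = ka c₀ exp(E_ads)`
with reference concentration c₀ = 1 mol/L so that ka/kd = exp(−E_ads) L/mol.
Exponents are capped at 700 with a warning.

## Kinetic Monte Carlo

**Event loop.** Gillespie direct method: total rate = Σ_s ka_s C_s N_sites,s
(arrivals) + Σ_j kd_j (desorptions); exponential waiting times; arrivals
placed uniformly on the sphere.  Overlap is tested in exact spherical
geometry: two caps overlap when their anchor separation is below the sum of
their cap half-angles (derived from footprint areas, consistent with the
effective-radius construction, and valid past 90°).  The insertion check is
O(N) per event; at the problem sizes used (≤ a few thousand adsorbed
particles) this needs no neighbour list.

**Displacement mode.** Arrivals are accepted with the logistic probability
p(ΔE) = e^(−ΔE)/(1+e^(−ΔE)), ΔE = E_in − Σ_j E_j over overlapped particles
(ΔE = E_in with no overlaps), evicting the overlapped set on acceptance.
This deliberately breaks detailed balance in one direction — one molecule
may evict many, never the converse — because the reverse event would require
simultaneous multi-molecule collisions that are never sampled.  Since
bare-surface arrivals now succeed only with probability p(E_ads), desorption
rates carry the same factor, keeping every equilibrium constant unchanged
(significant only for weak binders, E_ads ≳ −3 kBT).  Bare surface is
implicit water at affinity 0 kBT; all energies are relative to it.

**Quasi-equilibrium acceleration.** Species whose adsorb and desorb counts
both exceed n_eq = 100 within a 10⁴-event window, with net flux below 20% of
the one-way mean (displaced evictions count as departures), have ka and kd
multiplied by a common α < 1 capping their event rate at 10× the fastest
non-equilibrated species.  Any event of a non-equilibrated species reverts
the scaling and restarts the window.  Because forward and reverse rates
share α, equilibrium constants — and hence steady-state compositions — are
untouched; only the time axis of the scaled process is compressed.  All
parameters are configurable (`AccelerationConfig`).

**Summaries.** The first half of the run (configurable) is discarded as
burn-in; the remainder is time-averaged in 10 blocks giving per-parent
number densities N/(4πR²_NP) in nm⁻², mass abundances
M_i = 100 N_i MW_i / Σ N_j MW_j, and block standard errors.  The block
standard error underestimates the true error when a species' relaxation
time approaches the block length; the bundled benchmarks are sized so every
species relaxes many times per block.  One 64-bit seed feeds a single PCG64
generator; identical seeds give bit-identical event streams.

## Synthetic data and the milk benchmark

The fixture generator produces everything the pipeline needs with no
external data:

* **Synthetic PMFs** — softplus-style wall + Gaussian well + zero tail, with
  the global minimum exactly at the requested depth and position (default
  0.23 nm, matching the typical first-minimum position of metal-surface
  profiles).  Shape, not provenance: any smooth curve with these extrema
  exercises the same code paths.
* **Toy molecules** — single bead, dumbbell, rod, tetrahedron, with
  deterministic geometry; the glucose dumbbell at 0.52 nm separation doubles
  as the lactose model (both beads neutral, Hamaker off).
* **The milk system** — the published characteristics of the six most
  abundant cow-milk proteins and lactose (molecular weights, net charges at
  pH 7, milk concentrations, radii of gyration), the published
  minimum-energy orientation per protein on the three fcc aluminium facets,
  and the published corona compositions as reference vectors.  Real
  orientation heatmaps are not publicly tabulated, so protein entries are
  carried as single-orientation species from the printed minima with
  footprints π·Rg² — sufficient for ranking and bookkeeping, tagged as such
  in the bundle provenance.  The third facet's printed AS2C density row is
  arithmetically inconsistent with its printed mass-abundance column, so
  that surface is excluded from numeric checks.
* **Glucose well depth** — the real glucose–aluminium profile is not
  published numerically; the default −2.0 kBT gives lactose E_ads ≈ −2.1
  kBT, i.e. the weak, rapidly equilibrating binder the displacement and
  acceleration machinery is designed around.  A deep well (−6 kBT) makes
  lactose irreversibly tile the surface, contradicting the known corona
  ranking.

What passing tests do **not** show about real systems: protein flexibility
(rigid-body only — flexible caseins adapt to surfaces in reality),
pH-dependent charge assignment, PMF accuracy (synthetic shapes only), bulk
depletion (concentrations held constant), or absolute corona densities,
which require the full orientation heatmaps and the measured PMF data set.
Analytic and statistical properties (two-state occupancy, equilibrium
ratios, hard-sphere integrity, displacement monotonicity, acceleration
neutrality, determinism) are exercised on scaled-down particles (8–20 nm)
and 10⁵–3×10⁵ event runs — sizes chosen so every species relaxes many times
within a run while a full validation pass stays interactive.

## Known limitations

* The footprint is evaluated at a fixed 0.2 nm standoff; footprints of very
  elongated molecules in tilted orientations are sensitive to this choice.
* `parameterize_heatmap` groups orientations by θ (φ-averaged energies) by
  default; per-(φ, θ) species are available but multiply the species count
  by the φ-grid size.
* The quasi-equilibrium scaling follows the accelerated-superbasin idea in
  its simplest windowed form; pathological rate landscapes (three or more
  widely separated timescales) may see little speed-up, though never a bias.
* Desorption re-enters the bulk with no spatial correlation; rebinding
  effects at high concentration are not modelled.
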