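# Methods

## Model

Each protein is a rigid pseudo-hard sphere of diameter sigma decorated with
2-4 attractive surface patches (binding sites).  Everything is expressed in
reduced units: energies in the full well depth epsilon, lengths in sigma,
temperature T* = kB T / epsilon, density rho* = N sigma^3 / V, time
t* = t sqrt(epsilon / (m sigma^2)) with unit particle mass, and surface
tension in epsilon/sigma^2 (or kB T/sigma^2 after dividing by T*).

The pair potential is

* a cut-and-shifted Mie (50, 49) repulsive core that vanishes with zero
  slope at r = (50/49) sigma, making the spheres effectively hard at the
  temperatures of interest (T* ~ 0.1, where the r where U_core = T* sits
  within ~1.5% of sigma), and
* for every patch pair (a, b) an attractive well

      U_ab = -epsilon d_ab  phi(r)  Omega(cos theta_a)  Omega(cos theta_b)

  with d_ab in [0, 1] the affinity-matrix depth.  phi is a cos^2 bump
  centered at `well_position` = 1.03 sigma with half-width
  `well_halfwidth` = 0.09 sigma (compact support, so the attraction ends
  0.12 sigma beyond contact) whose maximum is exactly 1; Omega is a
  Gaussian in (1 - cos theta) whose half-width at half maximum is
  `angular_hwhm` = 0.3 rad.  theta_a is the angle between patch a and the
  center-to-center direction.

These choices pin down the two contracts the model depends on analytically:
a perfectly aligned full-strength bond has energy exactly -epsilon (the
well position lies beyond the core cutoff, so the core contributes nothing
at the minimum), and a patch binds at most one partner (two partners inside
one patch cone would overlap their cores; the residual double-binding
energy is bounded above by 0.05 epsilon, which the test suite checks by a
geometric scan).  All three parameters are exposed in `PotentialParams` and
in the run-config YAML.  The Gaussian tail of Omega is truncated below
e^-18 so the numba kernel and the numpy reference path agree bit-for-bit.

Forces and torques are analytic derivatives of the energy
(finite-difference-checked to 1e-6 relative error in the tests).

## Species catalog and mixtures

Six species with decreasing valency: 4-valency promiscuous (tetrahedral,
one site class), 4-valency selective (tetrahedral, two site classes placed
2+2 that bind only their own class on the parent species but promiscuously
across species), 3-valency good topology (coplanar sites at 120 degrees),
3-valency poor topology (orthogonal sites), 2.25-valency (good topology
with one site weakened to strength 1/4), and 2-valency (polar).  Site
classes are species-scoped labels so selectivity rules can be conditioned
on species identity.  Cross-class well depths combine site strengths by the
arithmetic mean (so weak-full = 0.625, weak-weak = 0.25).

The four mixture presets set species-pair affinities: `valency_driven`
(all pairs bind), `like_valency` (pairs bind iff their valencies differ by
at most 1), `non_competing` (two mutually inert 4-valency scaffolds, each
with one dedicated client; default pairing promiscuous-2.25v and
selective-2v, configurable because the published table is graphical), and
`competing` (non_competing plus both scaffolds bind the 3-valency
good-topology client).  Compositions default to equal particle counts per
species (32 each at desk scale); counts are config-exposed.

## Dynamics

Velocity-Verlet with an isotropic rigid-body rotation (inertia of a
uniform sphere, I = 0.1 m sigma^2; with isotropic inertia the free drift
is an exact rotation by omega dt).  NVT sampling uses a BAOAB-style
Langevin thermostat on both translational and rotational momenta (default
coupling time 0.1 t*), or a Berendsen velocity-rescale alternative.
Neighbor pairs come from a periodic k-d tree with a 0.3 sigma Verlet skin,
rebuilt when any particle moves half the skin.

The default timestep is dt = 0.001 t*: against the steep Mie(50,49) core
this conserves NVE energy to |dE/E| ~ 3e-4 over 10^4 steps, while
dt = 0.002 drifts ~2.6e-3 at T* = 0.09.  Langevin-thermostatted
(production) runs remain stable and correctly thermalized at dt = 0.002,
which the sampling-only workflows use for speed.  Nucleation and
coarsening are diffusion-limited; a Langevin coupling of 0.5 t*
(weaker friction) roughly triples the coarsening rate at equal step
counts and is used for the direct-coexistence workflows.

## Direct coexistence and the critical point

A slab at rho* = 0.5 occupying the central third of a 1:1:4 periodic box
is relaxed at fixed T*; per-frame density profiles along z are recentered
on the slab's periodic center of mass (circular mean) and averaged after
discarding the first half of the trajectory.  Recentering exists to remove
slab drift; it is disabled for homogeneous configurations, where centering
on density noise would imprint spurious structure.  Coexistence densities
come from a symmetric two-interface tanh fit with plateau parameters
bounded by 1.5x the profile maximum (which protects the fit when a small
slab deforms toward a droplet); uncertainties come from refitting 5
contiguous trajectory blocks.  The critical point is a joint least-squares
fit of the density gap to A (1 - T/Tc)^beta with beta fixed at the 3D
Ising value 0.325 (fitting beta from a handful of points is
ill-conditioned) and of the mean density to the law of rectilinear
diameters; points are weighted by their inverse block uncertainties, which
matters at desk scale where near-critical points are noisy.

## Surface tension

gamma = (Lz / n_interfaces) <Pzz - (Pxx + Pyy)/2>, the mechanical route
from the global pressure-tensor anisotropy of the slab run, with the
virial accumulated per pair as r_ij (x) f_ij (valid for the non-central
patch forces).  Uncertainties from 10-block averaging.  Curved-interface
corrections are out of scope.

## Condensate structure and kinetics

Particles are bonded when their total pair patch attraction is below
-0.1 epsilon; condensates are connected components of at least 10
particles (the bonded-network criterion matches the model's valency
semantics; the minimum size suppresses transient dimers/trimers).
Layering profiles measure per-species density versus distance from the
largest condensate's periodic center of mass - along the long axis for
slab geometry (the direct-coexistence default, where an x-y centroid of a
cross-section-spanning slab would be meaningless) or over spherical shells
for compact droplets.  The exchange-rate order parameter decimates frames
until condensate residents have diffused at least one molecular diameter
(mean squared displacement >= sigma^2), counts particles whose phase label
flipped between consecutive retained frames (in- and out-movers alike, the
reading most consistent with counting exchange events; the signed
alternative |Delta N| is also available), requires a flip to persist one
further retained frame (one-frame hysteresis against bond flicker), and
divides by the slab's interfacial area 2 Lx Ly.  Molar-fraction time
series track the composition of the largest condensate during nucleation
runs started from a homogeneous fluid.

Two scalar order parameters place a mixture in the
valency-difference/affinity-variance plane: the scaffold-client valency
difference (scaffolds default to the 4-valency species; pass each scaffold
separately for presets that form two condensates) and the population
variance of pairwise affinity scores over all 21 unordered species pairs
(homotypic included), where a pair scores the mean of its two valencies if
it binds and zero otherwise.

## Synthetic fixtures

Analysis code is validated against generators with exact ground truth: a
uniform ideal gas (binning and normalization), a two-phase slab sampled
from a double-tanh density (coexistence-fit round trip), a concentric
core-shell droplet (layering), and a scripted exchange trajectory with an
exact mover count per interval (exchange-rate identity).  These fixtures
emulate geometry and counting statistics only - they contain no
interactions or dynamics, so passing them validates the analysis
operations, not the physics of real trajectories.

## Desk-scale study conditions and what they show

The published phase behavior of this model family comes from runs of
thousands of particles over t* ~ 1e4-1e5.  The package's default test and
acceptance conditions are deliberately small, sized to one CPU: pure-system
phase diagrams use 144 particles and 2e5 steps (t* = 400) per temperature,
and the mixture presets use 64 particles per species (N = 384) over 3e5
steps (t* = 600) with the pressure tensor sampled every 100 steps.  At
this scale slabs equilibrate enough for tanh fits and the qualitative
phenomenology is reproducible across seeds: the critical-temperature
ordering across valencies, the scaffold-core/client-shell family layering,
the segregation (non-competing) versus client-bridged fusion (competing)
of the two-scaffold mixtures, the point-estimate reduction of every
mixture's surface tension below the pure scaffold reference, the faster
exchange of 3-valency clients relative to 4-valency scaffolds, and the
scaffold-enrichment of first nuclei.  What desk scale does not deliver:
per-species layering profiles sharp enough to resolve the full
six-species radial ordering (minor species' profile centers are dominated
by dilute-phase noise), surface-tension differences that exceed their
block-averaging uncertainties (closing those bands needs roughly an order
of magnitude more sampling), and the full transient peak-then-relax shape
of the scaffold molar fraction during nucleation.  Fitted critical
parameters carry ~5-10% scatter and coexistence densities are not
converged to the thermodynamic limit; tests therefore assert orderings
and contracts, not published values.

## Known limitations

No amino-acid sequence resolution, no explicit solvent, no multivalent
binding between a single patch pair (by construction), NVT/NVE only, and
no curved-interface surface tensions.  The exact potential parameters of
the published model are not public; the functional form here preserves its
stated contracts but absolute critical temperatures and tensions can
differ from the published ones at the few-percent level or more.
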