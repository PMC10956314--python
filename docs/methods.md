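# Methods

`mesocell` is a hybrid lattice/off-lattice spatial stochastic simulator
for cellular reaction–diffusion systems at the meso-scale. This note
describes the model, its numerical choices, the built-in study systems,
and what the validation suite does and does not establish.

## Representation and timestep cycle

Space is a box of cubic voxels (edge `h`, typically 0.01–1 µm) carrying
compartment labels; geometry is expressed entirely through per-voxel
compartment membership, so trimmed or nested shapes are voxel sets.
Species are either

* **bulk**: a real-valued molecule amount per voxel, for small abundant
  molecules (here: Ca²⁺), or
* **particles**: individually tracked point molecules with continuous
  positions, named binding sites and boolean state flags (here:
  calmodulin, CEACAM1, Lck).

Each timestep Δt executes, in a fixed order: (1) bulk diffusion,
(2) particle Brownian steps with reflection and microdomain partition
biasing, (3) reactions (unimolecular → bulk–particle →
particle–particle → bulk–bulk), (4) probabilistic transport events,
(5) immobilization events, (6) sources/sinks, (7) logging. One RNG
stream consumed in this order makes runs bit-reproducible given
(model, seed).

## Diffusion

Bulk fields evolve by explicit forward Euler on Fick's second law with
the 6-point face-neighbor stencil,

    N_i' = N_i + (D·Δt/h²) · Σ_j (N_j − N_i),

where the sum runs over face neighbors accessible to the species; flux
across an interface into a disallowed compartment is zero, so restricted
compartments act as reflecting boundaries and total amount is conserved
to round-off. The stability bound D·Δt/h² ≤ 1/6 is enforced at model
validation. Amounts are continuous reals, not integers.

Particles take independent Gaussian steps of per-axis standard deviation
√(2DΔt). Proposed positions are folded specularly at the domain boundary
and mirrored at the boundary plane of any voxel the species may not
occupy, with a retry cap of 10 after which the particle stays put.
Specular reflection preserves the uniform equilibrium distribution
(verified by a per-octant occupancy test).

Membrane-bound particles diffuse in-plane only: each membrane voxel of
the outer layer has an outward-normal (frozen) axis, assigned with
priority x→y→z at edges and corners, and a particle's frozen coordinate
never changes. Particles entering the membrane are anchored a small
offset (0.5 % of a voxel edge) inward of the membrane layer's
*inner* face — the physical picture of a receptor sitting on the
cytosol-facing membrane surface. This keeps membrane particles within
binding reach of partners confined to the adjacent voxel layer; with a
uniformly random depth inside the 0.2 µm membrane voxels, a reaction
radius of a few nanometres would almost never span the compartment
boundary. A 2-D step that would carry a particle past a cube edge is
reflected at the edge; particles do not migrate around corners onto
other faces.

## Reactions

**Unimolecular** events use the exact first-order probability
1 − exp(−kΔt) per step for particles, and the same deterministic
fraction per voxel for bulk reactants.

**Bimolecular particle–particle** reactions use an absorbing-sphere
scheme: every unordered reactant pair ending the step at separation
≤ σ_b reacts with probability 1 (pure Smoluchowski sphere; all rate
control is in the radius). Because positions are only inspected at step
boundaries, a fixed physical contact radius under-counts encounters at
coarse Δt; following the timestep-adjustment idea of Andrews & Bray
(Phys. Biol. 1:137, 2004), σ_b is calibrated *to the timestep* so the
discrete process reproduces the requested mass-action k. The calibration
solves the steady-state radial integral equation of the discrete process
(Gaussian relative step of per-axis std s = √(2(D_A+D_B)Δt), end-of-step
absorption at r ≤ σ) on a radial grid with an analytic 1 − A/r far-field
tail, the depletion amplitude A being fixed by a closed-form
self-consistency condition, then inverts k(σ) by monotone root finding.
Both analytic limits are recovered to well under 2 %:

* s ≪ σ: k → 4π(D_A+D_B)σ (Smoluchowski);
* s ≫ σ: k → (4/3)πσ³/Δt (well-mixed swept volume).

Requests whose radius would exceed 200 rms steps are rejected as
activation-limited (collision is no longer the rate-limiting
assumption at that resolution). Validation compares the calibrated
kinetics against second-order closed forms at two timesteps differing
5-fold, and shows the *uncorrected* radius k/(4πD) failing by tens of
percent at the coarser step — the motivating failure mode. Note that at
finite reactant density the encounter rate carries the classical
time-dependent Smoluchowski transient (∝ σ/√(πDt)); benchmark
measurements therefore use late measurement windows.

Pair matching is greedy nearest-first with each particle reacting at
most once per step — deterministic given positions, avoiding list-order
artifacts. Products of A+B→C are placed at the pair midpoint; reverse
dissociations place the two products at separation σ_u (default σ_b, so
products appear at contact; the resulting geminate-recombination bias is
accepted and a configurable multiplier is provided). A product species
that also appears among the reactants is treated as a catalyst: the
particle persists with only its pattern assignments applied.
Immobilized (trans-engaged) particles do not participate in
particle–particle collisions.

**Bulk–particle** reactions fire each matching particle with probability
1 − exp(−k·C_local·Δt), C_local being the bulk concentration in the
particle's voxel; each firing consumes one molecule from that voxel. A
firing the voxel cannot supply with a full molecule is cancelled: this
keeps free + bound amounts exactly conserved (the alternative, flooring
the voxel at zero, creates mass out of nothing at sub-molecule
occupancies). The scheme's accuracy improves with bulk diffusivity, as
local depletion around slow-mixing voxels vanishes (verified against
the well-mixed ODE over two decades of D).

**Bulk–bulk** reactions are deterministic per-voxel mass action,
ΔN = k·C_a·C_b·V·N_A·Δt, capped so no amount goes negative.

## Events

**Sources/sinks** act after diffusion: `clamp` pins a voxel at a target
concentration (Dirichlet), `influx` adds a fixed amount per step,
`absorb` zeroes the voxel.

**Transport** abstracts vesicle traffic as a single probabilistic event:
each matching mobile particle in the source compartment relocates with
probability p per step to a uniformly random position in a random
accessible voxel of the destination (mimicking vesicle delivery anywhere
on the target); a blocking state flag (e.g. ITIM phosphorylation)
vetoes the rule.

**Microdomain partitioning**: membrane sub-regions (lipid rafts) are
voxel sets with per-species entry/exit acceptance probabilities; a
denied crossing is reflected at the domain boundary plane. For a
symmetric random walk this yields the stationary density ratio
entry_bias/exit_bias inside vs outside — the basis of the two-state
balance test (occupancy A_in/(A_in + q·A_out) for entry 1, exit q).
All-unit biases are compiled away so they cannot perturb trajectories
through RNG consumption.

**Immobilization** is the trans-binding surrogate: matching mobile
particles immobilize at rate k_on (s⁻¹) and release at k_off;
immobilized particles skip diffusion and transport. The "clustered"
CEACAM1 count is, by definition, the number of currently immobilized
monomers.

## Built-in systems

### Cooperative calmodulin activation (well-mixed)

A 4×4×4 box of 0.2 µm voxels (0.8 µm cube, V = 5.12×10⁻¹⁶ L). Ca²⁺ is
bulk (D = 220 µm²/s, free calcium in cytosol); calmodulin is a particle
species (D = 25 µm²/s) with four sites N1, N2, C1, C2 organised as two
lobes. Binding within a lobe is sequential with positive cooperativity:
site 2 can bind only while site 1 is bound, expressed as state-dependent
bulk–particle rules with the statistical factors (2× first association,
2× dissociation from the full lobe) applied by the builder. Per-site T/R
rate constants are taken from Faas et al. (2011, Nat. Neurosci.
14:301–304) and stored in a provenance-commented YAML file; every
kinetics check is expressed relative to the well-mixed forward-Euler
oracle run with the *same* constants, so the validation surface is
constants-independent. (The fastest constant, the R-state N-lobe
association at 3.2×10¹⁰ M⁻¹s⁻¹, sits just above the 10⁷–10¹⁰ advisory
range and triggers a warning by design.) At 2 µM calmodulin these
constants give <1 % activated (CaM_4) calmodulin for total Ca ≤ 1.2 µM,
with 20 % activation requiring ≈11–12 µM — an order of magnitude above
physiological resting levels. An algebraic detailed-balance solver
provides equilibrium fractions independently of the integrator. Default
2 µM CaM ⇒ 617 particles; Δt = 1 µs.

### Calcium microdomains (quintile model)

A 10×10×10 lattice of 0.08 µm voxels split into five 2-voxel slabs
Q1–Q5. Four channel voxels on the Q1 outer face release Ca²⁺ every
step; the Q5 outer face absorbs; all other walls reflect. Release is
modelled as an *influx* of 0.3 molecules per channel voxel per step —
the channel rate is not published, and this single value was calibrated
once so the standing quintile-average gradient spans the reported
few-µM regime (measured ≈9 → 0.6 µM from Q1 to Q5; box average
≈1–2 µM). A literal 1 mM Dirichlet clamp at the channel voxels is also
available (`source_mode="clamp"`) but pins the whole box at hundreds of
µM in steady state — the steady profile between fixed boundary values is
set by geometry alone — which is incompatible with the few-µM regime
the system is meant to exhibit.

The characteristic microdomain behaviour is emergent: calmodulin mixes
across the box in ~13 ms while the loaded C-lobe releases its calcium
at only ~6.6 s⁻¹, so the *primed* (CaM_2) pool equilibrates to the
volume-averaged calcium and stays high (~70–75 %) even in Q5 where
local Ca is sub-µM; the N-lobe releases at ~2.5×10⁴ s⁻¹, so *activated*
(CaM_4) calmodulin exists only within the high-Ca halo near the
channels and decays within tens of µs of leaving it (≈30 % in Q1,
≈0 in Q5, monotone in between). One consequence of these off-rates is
that no measurable CaM_4 survives transport to Q5. Three channel
layouts (center / original / split) are provided; per-quintile
activation is insensitive to the choice (compared at 20 % relative with
a 1-percentage-point floor for near-zero quintiles). Default run length
3×10⁵ steps of 1 µs (0.3 s ≈ 2 C-lobe release times), averaging over
the second half.

### CEACAM1 clustering (raft and no-raft)

A 6×6×6 lattice of 0.2 µm voxels: membrane (outer layer, 2-D
diffusion), cytosolic interface (second layer; activated calmodulin
confined here), and a 2×2×2 core shared between a 2×2×1 organelle slab
(excluded region) and a 2×2×1 cytosol (the 6³ geometry cannot host two
one-voxel shells *and* a full central organelle *and* a distinct
cytosol). Species: CEACAM1 cis-dimers and monomers (D = 0.2 µm²/s,
membrane-bound; monomers carry a `phosphorylated` flag), Lck
(membrane), and pre-activated calmodulin CaM_4 (D = 25 µm²/s,
interface). Rules: catalytic dimer dissociation by CaM_4
(4×10⁷ M⁻¹s⁻¹ — set at the diffusion-influenced end so that dimer
turnover across the membrane/interface boundary is observable at the
validation timescale; the qualitative contrasts below do not depend on
its exact value), monomer dimerization (10⁶ M⁻¹s⁻¹ default, scanned
over 10⁴–10⁷), Lck phosphorylation of monomer ITIMs (membrane-scoped,
10⁶ M⁻¹s⁻¹), export/internalization transport at 10⁻³ per step with
internalization blocked by phosphorylation, and reversible monomer
immobilization (k_on = 1 s⁻¹, k_off = 0.1 s⁻¹) standing in for
trans-binding. The raft variant adds one 2×2-voxel lipid-ordered patch
per face (area fraction 0.11) with monomer-favouring (entry 1.0 / exit
0.2) and dimer-excluding (entry 0.2 / exit 1.0) biases; Lck starts
inside rafts and cannot leave. 50 dimers start in the cytosol. Full
runs are 2×10⁵ steps of 50 µs (10 s); validation uses 2×10⁴ steps,
where the qualitative contrasts (calmodulin-dependence of clustering,
Lck-independence, monotone growth of the clustered count, reduced
sensitivity of the raft model to the dimerization constant) are already
expressed.

## What the synthetic systems do and do not establish

The built-in models emulate the *mechanistic structure* of the study
systems — cooperative two-lobe binding, a standing source–sink calcium
gradient, raft partitioning with catalytic dissociation and transport —
at particle counts and run lengths where one CPU suffices. They do not
emulate cytosolic calcium buffering beyond calmodulin itself, membrane
crowding, receptor glycoforms, or downstream SHP1 signalling, and the
organelle is inert geometry. Passing tests therefore establish the
engine's numerical fidelity (diffusion, kinetics, conservation laws)
and the qualitative mechanism-level behaviours, not quantitative
predictions for real T cells.

## Numerical details and degenerate inputs

* Float serialization uses `repr`, so XML round-trips are bit-exact.
* `voxel_of` floors coordinates; positions live in the half-open box
  [0, extent). Reflection clamps to the largest representable
  coordinate below the boundary.
* Zero-diffusivity species never move; zero-rate rules are compiled
  away; empty compartments for a transport destination are a
  validation error.
* Bulk logging reports summed real amounts (not rounded); particle
  counts are integers.
* The binding-radius solver uses 121 radial nodes over 12 rms steps,
  trapezoid quadrature with the junction half-weight shared between the
  on-grid unknown and the analytic tail, and an 80-point sub-grid for
  the absorbed flux; D_sum = 0 falls back to the closed-form well-mixed
  radius.
* Random placement chooses a voxel uniformly, then a uniform position
  inside it; initial concentrations convert through the voxel volume
  (h³·10⁻¹⁵ L) and round to the nearest whole particle.

## Known limitations

* Membrane particles cannot cross cube edges onto other faces; each
  face is an independent 2-D system. Rafts are therefore placed on
  every face.
* The absorbing-sphere scheme with reaction probability 1 slightly
  over-correlates reaction events at high density; mass-action
  agreement is verified at the ~µM scale used by the study systems.
* Bulk–particle firing cancellation at near-empty voxels biases rates
  downward when a voxel holds less than one molecule; this is the price
  of exact conservation.
* The quintile model's channel release rate is a calibrated, not
  measured, parameter; conclusions robust to it (gradient monotonicity,
  primed-vs-activated separation, layout insensitivity) are the ones
  asserted by tests.
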