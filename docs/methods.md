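# Methods

## Model

Chromatin is modelled as a closed bead–spring ring of `N` monomers in
reduced units: monomer diameter `d = 1`, thermal energy `kT = 1`, monomer
mass `m = 1`.  Each monomer represents 500 bp of chromatin (about three
nucleosomes, a 15 nm bead); those genomic/physical conversions are metadata
only — the simulation itself never uses them.

The potential energy is a sum of four terms (energies in kT):

* **Backbone bonds.**  Consecutive monomers are joined by harmonic springs,
  `U = 25 (r − 1)²`.  A permanent chromatin loop is one extra bond of the
  same strength between its two anchor monomers, which keeps the loop bases
  effectively always in contact.
* **Bending stiffness.**  A three-point term `U = k (1 − cos α)` acts on the
  angle `α` between successive bonds.  The default `k = 3` gives a
  persistence length of ≈ 2.5–3 monomers (⟨cos α⟩ = coth k − 1/k);
  `k = 2` and `k = 4` are the flexible / stiff variants.
* **Excluded volume.**  Non-bonded monomers repel via the shifted, purely
  repulsive Lennard-Jones potential `U = 4 (r⁻¹² − r⁻⁶) + 1` for
  `r < 2^{1/6}`, zero beyond.  To emulate topoisomerase-II activity
  (occasional strand passage) the potential is softened above
  `E_cutoff / 2`:

      U_soft = (E_cutoff / 2) · (1 + tanh(2U/E_cutoff − 1)),

  capping the pair energy at `E_cutoff` (default 3 kT) so two fiber
  segments can thermally cross.  The interaction radius is floored as
  `r_t = (r¹⁰ + 0.3¹⁰)^{1/10}` to avoid the `r → 0` singularity; the floor
  shifts the potential negligibly at physical distances.  With
  `crossing_allowed = False` the unsoftened potential applies and crossing
  is forbidden; a `phantom` chain has no excluded volume at all.
* **Confinement.**  A spherical potential rising linearly at 5 kT per
  monomer diameter outside radius `R` imposes a target density φ.  The
  density parameter counts monomers per cubic diameter (number density):
  `N / ((4/3) π R³) = φ`, i.e. `R = (3N / 4πφ)^{1/3}`.  Default φ = 0.02,
  giving `R ≈ 28.8` for `N = 2000` (a sphere volume fraction of ≈ 1%).
  This convention — rather than a monomer volume fraction — is the one under
  which the reference dense-ring crossing checks at density 0.85 are
  meaningful (0.85 exceeds the 0.74 volume-fraction ceiling for spheres),
  and the one used by the simulation tooling this class of models was
  originally run with.

Nonbonded exclusions: repulsion is skipped only for ring-adjacent pairs
(their bond already holds them at the repulsion core); loop-anchor pairs keep
their repulsion in addition to the loop bond.  A switch
(`exclude_loop_anchor_repulsion`) removes it for sensitivity checks.

## Initialization

Starting conformations are provably unknotted rings grown on a cubic
lattice: starting from a 4-monomer square, a randomly chosen bond is shifted
one lattice unit in a random perpendicular direction (4 choices) and, if
both shifted sites are free, expanded into a kink, adding two monomers;
occupied targets are rejected and the move is redrawn (budget 10⁶ rejections
per growth step — never approached in practice).  No strand can pass between
the old bond and its kink, so every intermediate ring is an unknot; the
package certifies this with the knot determinant (below).

The grown ring is recentred and cast to continuous coordinates.  If its
extent exceeds the confinement radius (rare at these sizes) it is
pre-compacted by short non-crossing dynamics under a stepwise shrinking
confinement radius — excluded volume stays on and crossing off, so the
topology is preserved.  Loop bonds are then closed gently: capped-force
relaxation pulls the distant anchors together without destabilising the
integrator, followed by a short uncapped settle.  Production dynamics
therefore starts from an already-closed loop, as the equilibration discard
assumes.

## Dynamics

Sampling uses velocity-Verlet integration with an Andersen thermostat: each
step, each monomer's velocity is resampled from the Maxwell–Boltzmann
distribution with probability `1 − exp(−ν Δt)` (default rate ν = 0.1 per
time unit — a weak coupling, chosen because it measurably speeds
configurational mixing at identical kinetic energy; the thermostat strength
is a sampling-efficiency knob, not physics).  An optional Ornstein–Uhlenbeck friction step (the O-step of a
BAOAB splitting) is available through the `friction` parameter and is
applied in compounded form every 10 steps; it is off by default.  Both
thermostats preserve the canonical distribution — the contract is the
equilibrium ensemble, not trajectory realism, and simulated time is not
matched to chromatin kinetics.

The timestep is validated, not assumed: `validate_timestep` requires (i)
kinetic-energy conservation within 2% over a thermostat-free stretch after a
thermostatted warm-up, and (ii) conservation of the knot determinant in a
short non-crossing run of a small dense ring.  The soft-core wall is the
stiffest feature of the energy landscape (local curvature corresponding to
ω ≈ 20 in reduced units), which sets the default `Δt = 0.015`; at
`Δt ≈ 0.04` the total energy drifts visibly.

Conformations are recorded every `steps_per_block` steps ("blocks");
diagnostics (block-averaged kinetic energy, max bond length, mean monomer
displacement from the start) are logged for every block, and blocks before
`equilibration_blocks` are discarded.  `equilibration_check` finds the first
block after which the displacement signal (smoothed over 50-block windows)
changes by less than 2% per window.  Two schedules ship:

* **paper**: 80 000 blocks × 3000 steps, first 1000 discarded, 10 looped +
  2 loop-free runs — the full-fidelity protocol.
* **desk**: 8 looped + 2 loop-free runs of 900 blocks × 500 steps
  (Δt = 0.015, one block = 7.5 time units), first 600 discarded.  Identical
  physics; only the sampling depth differs.  Many short independent runs
  beat few long ones here, because windowed contact statistics decorrelate
  only as the global fold reorganises.  The production discard (~4.5k time
  units) was verified against local observables: contact probabilities P(s)
  and internal distances R²(s) at the loop scale are stationary well before
  the discard ends, while the *global* mean-displacement signal keeps
  creeping as the ring mixes inside the confinement sphere (it measures
  mixing, not local equilibrium).

Crossable scenarios (topo-II active, and phantom chains) are additionally
**pre-mixed**: after loop closure, `prepare_start` runs cheap phantom-mode
dynamics (40k time units at Δt = 0.05 — no steep core, so the larger step is
stable) so each production run starts from an independent, well-mixed global
fold instead of the compact lattice ring, whose memory would otherwise
persist far beyond any affordable discard.  For crossing-enabled runs the
topological state is free to change by construction, so scrambling topology
during the premix does not alter the target ensemble; non-crossing scenarios
skip the premix and keep the certified unknotted lattice start.

Runs are bit-reproducible for a given seed (single-threaded compiled
kernel).  Internally the integrator keeps the state in float32
structure-of-arrays form for SIMD throughput; forces agree with the float64
reference implementation (`model.total_energy_forces`) to ~10⁻⁶ relative,
far below thermal noise.  The neighbor search is a counting-sorted cell grid
with a Verlet skin; the candidate list is rebuilt only when the two largest
monomer displacements since the last build sum to more than the skin (a
rigorous validity criterion that roughly halves rebuilds compared with the
usual per-particle half-skin rule).

## Topology sentinel

Knottedness is monitored with the knot determinant |Δ(−1)| — the Alexander
polynomial evaluated at −1: 1 for the unknot, 3 for the trefoil, 5 for the
figure-eight.  The ring is first reduced by chord-shortening (triangle)
moves, removing any vertex whose triangle is pierced by no other segment —
a move that cannot change the knot type; degenerate (collinear) triangles
sweep no area and are always removable.  The reduced ring is projected along
a random direction (retried, with a tiny jitter, until the projection is
generic), the crossings of the planar diagram are collected with their
over/under assignment, and the Alexander matrix is evaluated directly at
t = −1, where the crossing-sign dependence drops out of the matrix rules, so
only over/under information is needed.  The determinant of an (n−1)-minor is
the invariant.  The full polynomial is deliberately not computed: the
determinant is enough to distinguish the unknot from simple knots and serves
as a cheap crossing sentinel.

## Analysis

* **Contacts.**  Two monomers are in contact when their distance is strictly
  below 2 diameters.  Pairs closer than 2 along the ring are excluded from
  heatmaps (at cutoff 2.0 nearest neighbours are trivially always in
  contact); the source text is silent on this and the choice is configurable
  and echoed in every report.
* **Heatmaps.**  Per-conformation contact sets accumulate into a symmetric
  N×N count matrix; frequencies are counts divided by the ensemble's
  conformation number, so looped and loop-free ensembles of different depth
  are commensurable.
* **Contact-frequency ratios.**  Looped-ensemble frequency divided by the
  matched loop-free frequency over a window:
  *insulation* — enhancer positions in the promoter-proximal third of the
  loop interior (anchors excluded; "third" counts ⌊(L−1)/3⌋ monomers nearest
  the promoter-side anchor), promoter outside at the E-P distance, averaged
  over ±3 monomers of separation.  The promoter side is not stated in the
  source; the two orientations are mirror images about the loop centre, so
  an `orientation="both"` option pools them for variance reduction without
  changing the estimand.
  *facilitation* — all pairs with separation within ±3 of the E-P distance
  whose midpoint lies within ±⌊(distance − L)/6⌋ monomers of the loop
  centre (±6 for the 50 kb / 30 kb case, ±20 at 90 kb).
  *intra-loop* — a single matrix cell, no averaging.
  Reported uncertainty is the standard deviation of per-run ratios across
  the independent looped runs; window contact counts are echoed so Poisson
  errors can be formed.
  The loop-free denominator has a second estimator,
  `noloop_estimator="ring_average"`, which replaces the window frequency by
  the ring average at the same separations: the loop-free ring is
  statistically translation invariant, so this estimates the same
  expectation while self-averaging over the whole ring — essential at desk
  scale, where a fixed 100-odd-cell window in a short run carries large
  slow-mode noise.  The default remains the plain window estimator.
* **Loop-base profile.**  The heatmap row at a loop anchor, divided by the
  same row of the loop-free map, as a function of signed genomic offset
  (a 4C-like track).
* **Radial density.**  Distances from the loop centre-of-mass to all distal
  monomers (outside the loop and more than 20 monomers from either base),
  binned at 0.5 diameters from 0, averaged over conformations.  The
  radial-position dependence imposed by confinement is removed by dividing
  bin-wise by the same histogram computed against a *shuffled* COM — the
  loop COM of the same conformation index taken from the next run
  (cyclically), which requires ≥ 2 runs.  A loop-free control repeats the
  procedure at the diametrically opposite ring position.
* **Simulated FISH.**  Per-conformation Euclidean distance between two
  tagged monomers, binned at 0.5 diameters from 0, with mean and cumulative
  distribution.  The loop-free control pair sits diametrically opposite the
  loop in the *same* looped ensemble, mirroring the radial-density control.

## Synthetic-data scope

All inputs are generated by the simulator itself; there is no external data.
The model is a homogeneous equilibrium fiber with permanent loops: it
emulates the contact statistics of a loop's neighbourhood inside a single
TAD, and deliberately omits sequence heterogeneity, chromatin-chromatin
attraction, supercoiling, loop formation/release kinetics, and any
calibration of simulated time to real time.  Passing tests therefore
demonstrate the polymer-physics consequences of a permanent loop under these
assumptions, not agreement with any experimental Hi-C or microscopy dataset.

## What desk scale resolves — and what it cannot

Contacts at 50 kb separation occur at a few ×10⁻⁴ per conformation per
pair, and they arrive in long-lived clusters tied to the slow global fold,
so the effective number of independent window events per desk run is small.
With 8 pooled looped runs the 50 kb ratios carry ~10–30% sampling error;
single-position insulation windows (loop midpoint, near-base) see only a
handful of events and can swing several-fold between seed sets, as can the
90 kb windowed ratios.

One systematic effect deserves note.  In the fully mixed equilibrium that
the pre-mixed desk runs sample, the loop-free contact rate at large
separations approaches a confinement *background* (any two well-mixed
points in the sphere).  This background dilutes facilitation (the measured
phantom-chain facilitation at 50 kb is ≈ 2.7; removing the background term
analytically gives ≈ 3.2) and makes insulation distance-*dependent* at
background-dominated separations (the loop's steric shadow removes the
background around the enhancer while the loop-free denominator keeps it).
Reference values quoted for this class of models appear to correspond to
ensembles whose distant-segment background is territorially suppressed —
i.e. not fully mixed across the confinement sphere, which very long runs
from compact starts can retain.  The package samples the model's true
equilibrium and documents the difference rather than tuning toward it.

## Numerical choices and limitations

* Quantitative acceptance tolerances are max(2 × combined sampling SE,
  15% relative), where the combined SE joins the Poisson term with the
  run-to-run spread.  The `paper` schedule removes the sampling limitation
  at ~400× the compute.
* Ratio uncertainties from two looped runs (`stderr` across runs) are
  themselves noisy; the echoed window counts give a better-behaved Poisson
  estimate.
* The lattice-growth initializer produces compact rings whose extent is
  usually already inside the confinement sphere for the shipped presets;
  the pre-compaction path is exercised mainly at high densities.
* `equilibration_check` on the global displacement signal is conservative
  by design; for contact-scale observables it can report "not saturated"
  long after local statistics are stationary (see Dynamics above).
* The knot determinant cannot distinguish knots with equal |Δ(−1)| (e.g.
  the unknot from knots with determinant 1 such as some composites); for
  crossing-sentinel purposes on short timescales this is immaterial.
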