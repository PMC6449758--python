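# Methods

`boolcell` simulates a population of mechanically interacting cells whose
phenotypes are driven by per-cell stochastic Boolean signalling, embedded
in a reaction–diffusion microenvironment. This note documents the model
layers, the parameters that matter, the calibration of the bundled TNF
cell-fate case study, and what the desk-scale test battery does and does
not demonstrate.

## Stochastic Boolean signalling

Each cell carries a Boolean network: binary nodes joined by AND/OR/NOT
rules. Dynamics are a continuous-time Markov chain on the state space:
a node whose value disagrees with its logic target flips after an
exponential waiting time with rate `rate_up` (toward 1) or `rate_down`
(toward 0); exactly one node changes per event (asynchronous update). The
Gillespie kernel samples this chain exactly; a vectorised ensemble driver
runs 10³–10⁴ trajectories in lock-step for fate-probability estimates.
Correctness is checked against the matrix-exponential solution of the
2^k-state master equation on networks of up to 8 free nodes.

Input nodes (here: TNF) carry no transitions of their own — the coupling
layer pins them from the cell's environment. Mutations are rate
overrides, not logic edits: over-expression is `rate_up = 1e6/min,
rate_down = 0` applied *unconditionally* (the rate fires regardless of the
logic target, the encoding of constitutive escape from regulation), and
knockout is the mirror image. Plain rate overrides (e.g. transcription
speed scaling) remain logic-gated.

Models are read from a documented subset of the MaBoSS two-file dialect
(node blocks with `logic`, `rate_up`, `rate_down`; `$`-symbols,
`is_internal`/`is_input` flags and per-node Bernoulli `istate`
probabilities in the config). Constructs outside the subset are rejected
with named errors rather than silently ignored.

## The reconstructed TNF cell-fate network

The bundled fixture (`data/cellfate.bnd/.cfg`) is a **synthetic
reconstruction**: the topology follows the published 2010 death-receptor
cell-fate logical model (TNF → TNFR → complex-II/CASP8 apoptosis branch,
RIP1→IKK→NFκB survival branch, RIP1K→ROS→MPT non-apoptotic death branch,
with cFLIP/BCL2/XIAP cross-inhibitions), restricted to TNF as the sole
input, and adds explicit mRNA intermediates (mXIAP, mROS) so that
NFκB-driven transcription is slower than protein-level signalling. A
`transcription_rate_scale` multiplies the mRNA activation rates; raising
it speeds both XIAP-mediated apoptosis inhibition and ROS production and
therefore shifts deaths toward NonACD.

Two deliberate departures from a literal published-model transcription:

* the *Survival* read-out is `NFkB | !DISC` and starts active — naive,
  unstimulated cells are proliferative, and Survival becomes an
  NFκB-dependent read-out only once the death-receptor pathway is engaged.
  With a bare `Survival = NFkB` read-out, untreated populations would be
  permanently cycle-arrested by the Survival→cycling output rule, which
  contradicts the basic behaviour the model must reproduce.
* rate values are calibrated, not measured. The calibration targets are
  the population-level behaviours of the case study: under sustained TNF
  roughly half of a cell ensemble commits to death within 24 h with all
  three fates populated; ~20% of cells commit to apoptosis without ever
  activating NFκB; apoptosis commits faster (median ≈ 2 h) than NonACD
  (≈ 3 h); without TNF there is no death. The frozen constants are in
  `cellfate.cfg` (protein steps 0.1/min, caspase-8 activation 0.035/min,
  apoptotic cascade 0.08/min, NFκB target induction 0.04/min, mRNA
  transcription 0.03/min with turnover 0.01/min, ROS/MPT 0.02/min).

## Receptor kinetics and coupling

Local TNF enters a three-pool linear scheme per cell: free ligand binds at
`k_on = 0.1`/min per (ng/mL) (mass removed from the cell's voxel), the
bound pool internalises at `k_int = 0.5`/min, and the internalised pool
clears at `k_clear = 0.05`/min. The network's TNF input node is 1 while
the internalised pool exceeds θ = 0.15 ng-equivalents. θ was chosen so
that the activation transition of short boundary pulses falls between
stimulus areas of 10² and 10³ ng·s/mL (no response at ≤ 120, partial at
300, near-total at ≥ 900) and a single 0.5 ng/mL × 10 min pulse still
stimulates part of the tissue, while a sustained 0.5 ng/mL bath
(internalised plateau `k_on·c/k_clear = 1.0`) sits safely above threshold —
a marginal threshold makes borderline cells flicker between stimulated and
relaxed states and artificially re-runs the commitment race.

Output rules: Apoptosis/NonACD nodes latch the corresponding death
program on first activation (the cell-level fate is irreversible even
though the node may later decay); Survival gates the cycle clock
reversibly; NFκB activity switches autocrine TNF secretion
(0.02 ng/mL/min into the cell's voxel by default) and permanently marks
the cell "activated" — the quantity reported by the activation census.
The secretion default matters: at 0.1 ng/mL/min the autocrine loop keeps
the medium saturated between injection pulses and erases the
pulsed-versus-continuous treatment contrast.

The three clocks default to diffusion 0.01 min, mechanics 0.1 min,
signalling 10 min. Per-cell signalling updates are staggered by a random
birth offset (config switch `stagger_signalling`) to avoid artificial
population-wide synchrony. The scenario suite runs diffusion and
mechanics both at 0.5 min — the implicit diffusion solver is
unconditionally stable and the mechanical relaxation times (≥ 2 min) are
well resolved — which keeps a 24-h spheroid run under ~20 s.

## Mechanics, cycle and death programs

Pairwise forces: repulsion `√(r_a r_b)(1−d/R)²` inside the radii sum R,
adhesion `√(s_a s_b)·√(c_a c_b)(1−d/(fR))²` out to `f·R` (f = 1.25), with
the adhesion strength chosen homotypic/heterotypic/matrix by the pair and
modulated by per-cell cadherin/integrin coefficients; the geometric-mean
combination makes adhesion a property of both partners. Overdamped Euler
integration with drag absorbed into the force scale; passive ECM spheres
move scaled by a friction coefficient (or are pinned) and can be degraded
by contact. Neighbour search uses a k-d tree whose pair list is visited
in the same order as the all-pairs path, so both give bitwise-identical
forces.

The cell cycle is a single-phase Erlang(4) timer (mean = strain
`cycle_duration`) gated on volume ≥ 95% of the doubled target; volume
compartments relax exponentially (0.05/min) toward phase-dependent
targets. An Erlang(4) timer yields an asymptotic population doubling time
of `ln 2 / (4(2^{1/4}−1)) ≈ 0.916` cycle means. Death programs: apoptosis
shrinks at 0.006/min and removes the cell below 5% of the reference
volume (~9 h); NonACD swells toward 1.5× and lyses after 6 h. Daughters
inherit the mother's network state bit-for-bit (resistance inheritance),
split volumes in half and redraw cycle lengths from their own RNG streams.

Reproducibility: one master seed; each cell's stream is keyed by (seed,
cell id), so a cell's trajectory does not depend on how many unrelated
cells divided before it. Identical config + seed reproduces output CSVs
bitwise. In 2-D mode z is frozen and the same spherical volume–radius map
is used (an 8.4 µm default cell radius from the 2494 µm³ reference
volume).

## Microenvironment

Substrates live on a regular voxel mesh (default edge 20 µm). Diffusion
uses one backward-Euler tridiagonal sweep per axis (operator splitting),
then exact exponential decay; zero-flux boundaries conserve mass to
machine precision and a point source reproduces the heat kernel to < 2%
of peak. Default transport constants are reconstructions, exposed in
config: TNF D = 1200 µm²/min, λ = 0.0275/min; oxygen D = 6000 µm²/min
with a fixed 38 mmHg boundary. Treatment injection is a Dirichlet rim:
while a schedule is on, boundary-adjacent voxels are held at the scheduled
concentration; while off, at zero, so the substrate washes in and out as
in a perfused chamber. Sampling is nearest-voxel (no interpolation),
matching the voxel-density semantics. The ECM density variant never
diffuses; cells degrade it first-order and deposit at a constant rate,
clamped to a maximum.

Oxygen-threshold necrosis: a proliferative cell whose local oxygen is
strictly below the strain threshold (5 mmHg default) commits to NonACD.
The per-cell uptake default (2/min) is calibrated so that a hypoxic core
forms at the reduced spheroid radii the test battery uses; at the
published radii (200 µm) a proportionally lower uptake gives the same
core-and-rim structure.

## Scenario calibration and desk scale

Scenarios default to reduced sizes (disk 100 µm, spheroid 50 µm —
roughly 100–150 cells initially) so the whole battery runs in minutes on
one core; publication radii (400/100/200 µm) remain available via
`full=True` or an explicit radius.

Two distinct growth calibrations are deliberate. The monolayer line uses
`cycle_duration = 1048 min`, giving a measured population doubling time of
≈ 16 h in sparse 2-D growth. The spheroid scenarios use 780 min, giving
the ≈ 4.5-fold expansion in 24 h that the spheroid experiments show.
These two observations imply different effective cycle times (16 h
doubling cannot produce 4.5× in 24 h), so the package treats them as two
cell-line calibrations exposed through the same strain parameter.

The cell-sorting assay mixes a strongly junction-forming strain (homotypic
adhesion 4.0) with a weakly adhesive one (0.5), cross-adhesion the
geometric mean, inside a pinned ring of passive ECM spheres, with equal
random motility (2 µm/min) for both and a longer adhesion reach
(interaction multiplier 1.5) than the growth scenarios. The motility is
the annealing noise: it can unbind weak contacts but not strong junctions,
so strong clusters coarsen while weak cells are displaced outward; the
mean radial position of the strong strain ends smaller. At ~300 cells
this ordering is reproducible across seeds; at a handful of cells it
drowns in cluster drift.

## Known limitations

* The fixture network's rates are calibrated to population behaviour, not
  fitted to molecular kinetics; individual node trajectories should not be
  over-interpreted.
* No contact inhibition of growth: crowding affects cells only through
  substrates and mechanics, so purely mechanical competition for space
  does not limit proliferation.
* Clonal competition for oxygen between mixed strains is weak at the
  smallest spheroid sizes: a 25% pro-survival clone changes the shared
  oxygen field of a ~50 µm spheroid by less than the seed-to-seed
  variability of the wild-type census. The suppression-under-competition
  contrast becomes reproducible from roughly a 100 µm radius (~10³ cells)
  upward, which is the size the test battery uses for that check.
* Dead cells free their volume instantly on removal; there is no debris
  field.
* The monolayer dose–response at reduced disk radius reproduces the
  no-response/full-response window (10²–10³ ng·s/mL) but its steepness
  differs from the full 400-µm geometry, where TNF penetration across a
  larger tissue broadens the transition; the published Hill-coefficient
  sweep is therefore a long-running job, while the test battery gates the
  fitting routine itself on noiseless parameter recovery.
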