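# Model and methods

`mtcrosstalk` simulates 2D mesenchymal cell migration driven by
microtubule–actin crosstalk. This note documents the model, its numerical
treatment, the reconstructed parameters and their defaults, and what the
synthetic study conditions do and do not establish.

## The model

**Geometry.** The cell boundary and the nucleus are closed bead–spring
loops (default 100 and 50 beads; initial radii `Rcell = 7 um`,
`Rnuc = 3 um`). A point centrosome anchors the minus ends of `Nmt`
microtubules (MTs), each a bead chain with bead spacing
`sigma_mt = 0.5 um`. Everything lives in the plane, in micrometers,
seconds and piconewtons; drags are `pN s/um`, so a bead with `gamma = 1`
moves at 1 um/s under 1 pN.

**Passive mechanics.** Bonds are Hookean (`ks`, rest length set by the
initial geometry); each vertex carries a discrete worm-like-chain bending
energy `kappa/(2 l0) (theta - theta0)^2` with `theta0` the regular-polygon
exterior angle for the rings and zero for MT chains. Steric exclusion is a
purely repulsive truncated-shifted Lennard-Jones (WCA) force, cut at
`2^(1/6) sigma`, applied between: MT beads and either ring, membrane and
nucleus beads, non-neighbor membrane pairs (self-avoidance), any bead and
an obstacle/wall surface, and the centrosome and the nucleus. Bead-bead
pair forces are capped at `f_cap = 0.75 pN`: the cap engages only at
unphysical overlap depths, is kept well below `ks*sigma` so a jammed
contact can never collapse a bond, and bounds both the contact stiffness
(`~13 f_cap / sigma`) that limits the stable timestep and the force a
stack of interpenetrating filaments (there is no MT-MT excluded volume)
can pile onto a single ring bead. Rigid surfaces get their own scale:
`f_cap_wall = 6 pN` with a linear depth penalty below the surface
(`f_cap_wall (1 - 2g/sigma)` at gap `g < 0`) — a bead touches at most a
couple of surfaces, so the larger cap stays stable, and it prevents bond
tension from pulling a taut membrane chord into a pillar. Both rings carry an
area-pressure term `E = k_area (A - A0)^2 / (2 A0)` (strong for the
nucleus, weak for the membrane): without interior support a bead-spring
nucleus flattens into a zero-area crescent under aster pushing and loses
the MT-shadowing and pore-gauging roles central to the model; the weak
membrane term represents osmotic/cortical area regulation.

**Microtubule dynamics.** Plus ends switch stochastically between growth
(`vg = 0.1 um/s`) and shrinkage (`vs = 0.2 um/s`) with catastrophe rate
`fc` and rescue rate `fr = 0.04 1/s`. `fc` is not a free parameter: it is
solved from the target mean length through the bounded two-state law
`<L> = vg vs / (fc vs - fr vg)`, because the study conditions are stated
as mean lengths (3, 9.3, 16 um), not rates. Beads are added/removed at
the plus end in `sigma_mt` quanta through a sub-bead accumulator. A
filament that shrinks to zero re-nucleates at the centrosome in the growth
state along a fresh uniformly random direction, so the filament count is
conserved. Lengths are capped at `4 * lmt_target` by a forced catastrophe
(a bound required by the padded array layout; the free-length exponential
tail beyond four mean lengths carries ~2% of the mass, and the free-MT
length-law check runs uncapped).

**Growth at contact (tip gliding).** A new bead is normally placed one
`sigma_mt` beyond the tip along the terminal tangent. If that position
would press deeper into the membrane, nucleus, a wall or an obstacle than
the current tip, the growth direction is projected onto the local surface
tangent — the tip glides along the surface, which is how filaments wrap
around the nucleus and run along channel walls. Head-on contact (within
~11 degrees of the surface normal, or a blocked deflection) stalls
polymerization with the accumulator held at the addition threshold;
growth resumes once bending rotates the tip away. Naive straight-ahead
placement let pressed tips thread the membrane ring and wedge it open;
contact-stalled, surface-deflected growth removes that failure mode while
preserving the buckling and gliding phenomenology.

**Crosstalk.** Each step counts, for every membrane bead, the MT plus-end
tips within `r_signal = 1.12 um` (twice the WCA cutoff of `sigma_mt` — the
model's tip–membrane contact criterion), split by dynamic state. Growing
tips impose an outward *active velocity* `v_prot0 * n_grow` along the
outward normal (actin polymerization); shrinking tips impose an inward
*force* `f_contr0 * n_shrink` (myosin contraction). The velocity/force
asymmetry is deliberate and follows the crosstalk rules the model encodes.
Counts pass through an exponential memory trace with `signal_tau = 20 s`
by default — cortical signals persist briefly after a tip moves on, which
steadies protrusion against single-filament noise and lets retracting
tips deposit contraction along the cortex they traverse; setting
`signal_tau = 0` recovers instantaneous counts.

**Nucleus–membrane coupling.** Nucleus bead `j` is linked to membrane
bead `round(j * n_mem/n_nuc)` by a Hookean spring (`k_couple`, rest
length `Rcell - Rnuc`), fixed at t = 0. The fixed pairing (rather than
nearest-neighbor re-pairing) transmits the rear drag that pulls the
nucleus and trailing membrane after the advancing front; re-pairing would
let the nucleus spin freely.

**Dynein.** Motors occupy a fixed random subset of ring beads (fractions
`rho_cortex`, `rho_nuc`, chosen once per seed). An unoccupied anchor binds
the nearest MT bead within `r_capture = 1 um` at rate `k_on`; a bound
motor walks toward the minus end at `v_motor` and pulls through a
zero-rest-length spring `k_motor`, applied to the anchor bead and, with
lever-rule weights, to the two MT beads bracketing the attachment point.
It detaches at rate `k_off`, when the spring load exceeds `f_stall`, when
the plus end shrinks past it — or when it reaches the minus end (end
dissociation). The last rule is a deliberate choice: a motor permanently
anchored at arc 0 forms a standing spring between the cortex and the
centrosome that ratchets membrane beads into the dense aster core;
with end dissociation the pulling force is still delivered to the
centrosome through filament tension during the walk.

**Equations of motion.** All beads follow overdamped first-order dynamics
`x(t+dt) = x(t) + dt (F/gamma + v_active)` with no thermal noise:
stochasticity enters only through dynamic instability and motor kinetics
(an assumption of the model class). Minus-end beads are constrained to
the centrosome; the force they accumulate is applied to the centrosome
(drag `gamma_cen = 10`, an aster-scale value — the centrosome integrates
the minus-end forces of every filament), after which minus ends are
re-pinned.

## Numerical treatment

* **Timestep.** `dt = 0.01 s` with the stiff *local* elasticity (bond
  stretching and bending of all three chain families) sub-cycled at
  `dt/n_sub` (`n_sub = 6`). The stiffest mode of a bead-spring chain is
  the bending zigzag at rate `kappa pi^4/(gamma l0^4)`; parameter
  validation rejects any configuration whose zigzag rate times the
  substep exceeds 1.5, whose spring relaxation rate times the substep
  exceeds 0.1, or whose switching rates are unresolved. The slowly
  varying forces (steric, motors, crosstalk, coupling, area pressure) are
  held constant across the step.
* **Guards.** Any bead displacement exceeding `sigma_mt/2` per step
  aborts with a "timestep too large" error (implemented as the sum of
  per-substep maxima, an upper bound on any single bead's step motion, so
  a healthy fast-then-slow elastic recoil within one step does not trip
  it); non-finite coordinates abort likewise.
* **Neighbor lists.** Verlet pair lists with a 0.6 um skin, rebuilt by a
  uniform spatial grid whenever any bead has drifted more than half the
  skin (and at every recording boundary, which makes snapshot/resume
  bit-exact). Freshly added plus-end beads are patched into the lists
  immediately with an enlarged search radius and an era stamp that
  invalidates entries for removed beads.
* **Determinism.** One seed drives three independent PCG64 substreams
  (initialization, MT dynamics, motors), so toggling motors does not
  shift MT randomness. Runs are bit-reproducible and resumable from JSON
  snapshots that include the generator states.
* **Two code paths.** The public modules hold readable vectorized numpy
  implementations of every operation; the engine runs compiled (numba)
  kernels. The test suite advances both paths on the same uniform-variate
  stream and requires agreement at 1e-8, and checks forces against
  numerical-gradient and brute-force-pair oracles.

## Parameters

Printed, fixed values: `Rcell = 7`, `Rnuc = 3` (the study text calls
these "diameters" in one place but uses `A0 = pi Rcell^2`; both are
treated as radii), `fr = 0.04 1/s`, `sigma_mt = 0.5 um`, the
`2 x 1.12 sigma_mt` contact criterion behind `r_signal`, mean lengths
{3, 9.3, 16} um, filament numbers 25–200, obstacle radii {4, 5} um and
pitches {20, 30} um, channel widths (10/10, 10/6, and {2,4,6,8} um), the
whole-cell 5.0 um entry rule, and the directed-migration classification
(`alpha > 1.7` and `dphi < 0.9` on 300-s windows).

Everything else is reconstructed (the full original force laws are not
available) and tagged as such in `mtcrosstalk.params.PROVENANCE`. The
defaults were chosen to keep the integrator stable at `dt = 0.01 s` and to
reproduce the model's qualitative regimes: polarized, roughly ballistic
migration with the centrosome-forward configuration for regular MTs, cell
area within ~10% of `pi Rcell^2`, aspect ratios in the 1.1–1.5 range, and
filament-scale behaviors (buckling at ~`pi^2 kappa/L^2`, gliding along
surfaces, motor-driven centrosome pulling). Key values: `ks = 20 pN/um`
for all bonds, `kappa_mem/nuc/mt = 0.2/0.35/1.5 pN um^2`,
`eps_wca = 0.05 pN um`, `k_couple = 2 pN/um` (rear retraction flows
through the nucleus coupling, so this constant sets the persistence
plateau for regular MTs), `k_area_nuc = 50` and `k_area_mem = 20 pN/um`,
`v_prot0 = 0.2 um/s`, `f_contr0 = 0.12 pN`, dynein `rho = 0.1/0.2`,
`k_on/k_off = 1/0.5 1/s`, `v_motor = 0.3 um/s`, `k_motor = 1.5 pN/um`,
`f_stall = 1.5 pN`, drags `gamma_mem/nuc/cen/mt = 1/5/10/6`.

## Study conditions and problem sizes

The bundled experiment helpers and the acceptance script run scaled-down
replicate counts and durations chosen as this package's own working
sizes: the acceptance script uses 1800-s free-space runs recorded every
5 s (360 frames, ~30 usable MSD lags) with 5 replicates per condition;
the in-suite regime ensembles use 1200-s runs with 3 replicates; channel
devices use a 16-um loading stem (the stem width is not printed in the
study; the arms carry the printed widths) with a 0.1 um/s chemotactic
bias and 2000-s horizons; the free-length law checks use 64-512 filaments
for 1e4-1e5 s.

## What the synthetic conditions do and do not show

The generator IS the model: all inputs are simulator-generated, so the
tests establish internal consistency (force laws, statistics of the
dynamic-instability process, estimator correctness on fixtures with known
statistics) and regime-level phenomenology, not agreement with any
particular cell type. Real cells have finite-Reynolds cortical flows,
adhesion dynamics, 3D geometry, MT-length regulation and signaling
pathways that this model deliberately omits. Within the model itself, two
known gaps remain at the default calibration (see the limitations below).

## Known limitations

* The posterior-centrosome configuration for long MTs (centrosome
  trailing the nucleus, polarity angle peaking above 90 degrees) does not
  self-organize robustly at this calibration: tip gliding distributes
  growing tips along the whole cortex rather than accumulating them at
  the distal pole, so the centrosome-forward attractor dominates for all
  mean lengths. The polarity-angle distributions for long MTs are
  therefore biased toward the centrosome-forward side.
* Short-MT (3 um) cells remain weakly persistent rather than fully
  diffusive over the simulated horizon; their persistence length is far
  below the regular-MT case, but the local MSD exponent stays above 1 on
  300-s windows.
* Very dense asters (200 filaments of 16 um in a 7-um cell) operate near
  the displacement guard; jams of many capped contacts on single nucleus
  beads set the nucleus drag and pair-cap defaults.
* Whole-cell channel entries (the 5-um rule) do not complete within
  simulated horizons up to ~6000 s at this calibration: under chemotactic
  bias the cell reaches a junction, extends protrusions into the openings
  and straddles the splitter, but does not commit and fully translocate.
  The path-choice statistics of the channel devices are therefore not
  reproduced by the bundled scaled-down ensembles; the device builders,
  entry scoring and choice statistics are exercised and tested at the
  machinery level.
* With crosstalk gains set to zero a weak residual drift remains
  (~2-3 um per 1200 s; dynein kinetics plus aster pushing with the
  centrosome held off-center by the nucleus), three-to-four-fold smaller
  than crosstalk-driven migration but not strictly zero.
* No MT–MT interactions (as in the source model class); filaments
  interpenetrate freely.
* 2D only; no substrate adhesion field; no thermal noise on beads.
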