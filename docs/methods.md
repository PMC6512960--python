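# Methods

`loopsim` simulates interphase chromosome folding by loop extrusion: cohesin-
like loop-extruding factors (LEFs) on a 1D chromatin lattice, directional
CTCF-like barriers, a coupled bead-spring polymer model, and the Hi-C-style
observables used to compare perturbation phenotypes.

## 1D LEF dynamics

The chromatin fiber is a lattice of `n_sites` sites of `site_size` kb
(default 10 kb, one site per polymer monomer).  A LEF occupies two sites (its
legs) and grows its loop by moving the legs apart.  Four parameters govern
the dynamics:

| parameter      | meaning                                            | units |
|----------------|----------------------------------------------------|-------|
| `velocity`     | total loop-growth rate of one LEF (both legs)      | kb per time unit |
| `lifetime`     | mean chromatin residence time                      | time units |
| `separation`   | mean genomic spacing of bound LEFs                 | kb |
| `strength`     | barrier blocking probability (= 1 − permeability)  | — |

Two derived quantities: the *processivity* `lifetime × velocity` (mean loop an
unobstructed LEF extrudes before unbinding, exact by construction) and the LEF
number `round(n_sites × site_size / separation)`, held constant: an unbinding
LEF instantly reloads at a uniformly chosen free adjacent site pair, realizing
exchange with a nucleoplasmic pool of fixed effective size.

**Discretization.** One simulation step is the time in which an unobstructed
LEF grows by two sites (one per leg), i.e. `2·site_size/velocity` time units.
Per step each LEF (in a fresh random order) first unbinds with probability
`1/lifetime_steps` where `lifetime_steps = processivity/(2·site_size)`;
otherwise each leg (left first, then right) attempts one outward move, which
fails silently when the target site is occupied by another leg, off-lattice,
or a blocking barrier fires.  Loop sizes are recorded at unbinding as the
*inclusive* span `(right − left + 1)·site_size`; with the unbind-then-move
ordering this census makes the mean recorded loop equal the processivity
exactly for every lifetime, not just asymptotically (the exclusive span would
undercount by exactly one site).

**Barriers.** A barrier occupies a site and blocks entry attempts by legs
translocating in its blocked direction; an inward-pointing CTCF motif at the
left boundary of a TAD maps to `blocked_direction="leftward"` (BED strand `+`).
Two halting modes:

* `transient_halt` (used by the scenario presets): the first encounter halts
  the leg with probability `strength`; a halted ("pressing") leg then remains
  halted with probability `strength**retests_per_step` on each later step.
  The re-test exponent (default 10) is a coarse-graining correction: the
  10-kb hop of this lattice aggregates ~10 sub-site (~1 kb) hops of the
  underlying fiber, each an independent chance to slip past a barrier whose
  occupancy by its blocking factor turns over quickly.  Without it, a
  strength-0.9 barrier would still block half of all legs for most of their
  lifetime at this lattice scale, and CTCF depletion would not abolish TADs.
  With it, dwell times are ~20 steps (≈ 2 WT lifetimes) at strength 0.995 but
  ~1.5 steps at strength 0.9 — reproducing the qualitative contrast between
  near-absolute and weakened barriers at the printed strengths.
* `capture_until_unbinding` (library default for hand-built configs): the
  single first-encounter draw at probability `strength` decides; a captured
  leg stays halted until its LEF unbinds.

**Exact oracle.** For systems with at most ~1e5 joint configurations,
`transition_matrix_small`/`exact_stationary_small` enumerate every LEF
configuration (leg positions plus pressing/captured flags), build the exact
one-step transition matrix by averaging the sequential update over all LEF
orderings, and power-iterate (with 1/2 laziness to remove periodicity) to the
stationary distribution.  The engine's long-run occupancy is validated against
this oracle to < 1e-2 total variation.

## 3D polymer model

Beads of one monomer diameter (10 kb) joined by harmonic bonds
(`k = 30 kT/d²`, rest length 1 d); LEF loops add identical harmonic bonds
between the current leg monomers.  Excluded volume is a *soft-core* repulsion
`E(r) = ε(1 − (r/σ)²)² for r < σ` with `ε = 3 kT`, `σ = 1 d`: overlap energy
is bounded, so chains can cross and the topology never locks.  The chain is
confined to a sphere at monomer volume fraction 0.2 (radius
`(N/(8·0.2))^{1/3}` d) by a harmonic wall (`k = 5 kT/d²`).  Dynamics are
overdamped Euler–Maruyama with `dt = 0.01 d²γ/kT` (auto-capped at
`0.5 γ/k_bond` for stability).  Thermal increments are uniform random numbers
with matched variance (weak order-1 convergence depends only on the first two
noise moments); pair forces use a Verlet neighbour list with a 1-d skin
rebuilt every 10 steps.

**Coupling.** One LEF step alternates with `steps_per_1d = 250` integrator
steps; loop bonds are rebuilt from the live leg positions each LEF step.  A
coupled run equilibrates for `max(2·lifetime_steps, 5·n_sites)` LEF steps
(covering LEF turnover and chain traversal; at scale 0.1 that is 1800 steps)
with LEFs loading fresh, so loops grow in gradually and no stretched bond is
ever introduced.  Conformations are sampled every 10 LEF steps, a cadence
chosen to exceed the TAD-scale Rouse relaxation (~12 LEF steps) so successive
samples are weakly correlated.

Confined runs start from a deterministic space-filling boustrophedon
("compact spiral") conformation that already sits at the confined equilibrium
density; starting from a random walk instead leaves chain-scale modes
relaxing for far longer than any TAD-scale observable needs.  Unconfined runs
start from an exact ideal random walk.

**RNG streams and replicates.** The 1D dynamics and the 3D thermal noise
draw from two independent streams spawned from the run seed, so the 1D
trajectory of a run is invariant to 3D protocol details and vice versa.
Slow chain-scale conformational fluctuations decorrelate only a few times
per production window at desk scale (the 2–3 Mb contact statistic drifts
±40% between quarters of a run), so heavily compared conditions are run as
several replicate seeds and their ensembles pooled before computing P(s) and
insulation; identical-noise pairing across conditions was tested and does
not help (the coupled dynamics are chaotic, so shared noise realizations
still diverge).

## Observables

* **Contacts**: monomer pairs within a capture radius of 2 monomer diameters
  (exposed everywhere; the qualitative phenotypes are insensitive to it
  between ~1.5 and 3 d).
* **Contact map**: ensemble contact counts binned genomically (default one
  10-kb bin per monomer), symmetrized, with each monomer's trivial
  self-contact once per conformation on the diagonal.
* **P(s)**: per-separation contact counts divided by the number of locus
  pairs at that separation (a probability), averaged over log-spaced bins at
  8 bins/decade with geometric centers, optionally normalized to 1 at the
  10-kb anchor.  The *shoulder* metric reports the log-log slope over
  100–500 kb and the per-bin ratio between a perturbation and its reference.
* **Insulation**: sliding w×w diamond (window 100 kb) mean contact frequency,
  normalized by the profile mean; minima mark TAD boundaries; bins within one
  window of the map edge are masked.
* **Corner peaks**: observed/expected at the pixel joining two barrier bins
  (±1-bin pixel box over a flank-3 ring at matched diagonal distance,
  excluding near-diagonal pixels).
* **Flames**: the barrier-anchored row segment (2..L bins off-diagonal,
  default 300 kb) over distance-matched segments anchored 3–5 bins away.
* **Orientation preference**: mean corner-peak score over convergent pairs /
  mean over divergent pairs.  A *convergent* pair is (leftward-blocking
  upstream, rightward-blocking downstream): both legs of a LEF between them
  can be halted, which is what builds a corner peak.

All ratio scores are invariant under rescaling the map.

## Scenario presets

All presets: 36-Mb chain (3600 monomers at 10 kb), barriers every 300 kb with
alternating orientations starting leftward-blocking (so consecutive pairs
alternate convergent/divergent and TADs carry corner peaks), 250 integrator
steps per LEF step, `transient_halt` barriers.

| scenario   | processivity | separation | strength |
|------------|--------------|------------|----------|
| `wt`       | 200 kb       | 200 kb     | 0.995    |
| `dcohesin` | 200 kb       | 2 Mb       | 0.995    |
| `dctcf`    | 200 kb       | 200 kb     | 0.9      |
| `dwapl`    | 1 Mb         | 150 kb     | 0.995    |

`scale_factor` shrinks the chain while preserving barrier density, LEF
density and processivity: scale 0.1 is a 3.6-Mb chain with 360 monomers,
12 barriers and 18 LEFs (for `wt`).  The exact orientation pattern among the
300-kb-spaced barriers is a model choice (alternating), fully specified in
the preset and overridable via a barrier table.

## Desk-scale validation protocol

The automated checks run every preset at scale 0.1 with 200 conformations
sampled every 10 LEF steps after 1800 equilibration steps (~1 minute per
condition on one CPU).  The wild type, the CTCF depletion and the
barrier-free control — the conditions entering ratio and noise-floor
comparisons — are run as three replicate seeds each and pooled into
600-conformation ensembles.  What these desk-scale runs can and cannot
show:

* TAD/peak/flame contrasts and P(s) band contrasts between conditions are
  robust at this scale and sample size.
* Absolute P(s) values at separations approaching the chain length are
  finite-size limited; only paired comparisons are asserted there.
* The generator emulates none of the complexities of real Hi-C data
  (ligation noise, balancing artifacts, compartments, replication state), so
  passing checks demonstrate the model's internal predictions, not agreement
  with any experimental map.

Boundary "presence" is operationalized as the local insulation depth — the
median of the profile 50–150 kb away minus the minimum within ±1 bin of the
barrier — exceeding twice the standard deviation of the barrier-free control
profile; "absence" as mean depth below that noise floor.

## Back-of-envelope calculators

`velocity_estimate(steps_per_sec, bp_per_step, n_motors)` converts measured
SMC stepping kinetics to kb/min (2 steps/s × 150 bp × 1 motor ≈ 18 kb/min;
two motors, 36 kb/min).  `atp_budget(n_extruders, atp_per_extruder,
atp_production)` returns the total extrusion ATP rate and its percentage of
cellular ATP production (1e5 extruders × 2 ATP/s against 1e9 ATP/s ≈ 2e5
ATP/s ≈ 0.02%).

## Known limitations

* One-sided (anchor + motor) extrusion, loading-site bias, LEF bypassing and
  variable LEF number are out of scope by design.
* The soft-core chain is crossable; entanglement effects are absent.
* The 10-kb lattice cannot resolve sub-TAD features below ~30 kb.
* Full-scale (36-Mb) coupled runs are supported but slow on one CPU; the
  validation suite uses density-preserving scaled systems instead.
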