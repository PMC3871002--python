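# Methods

## Model representation

The cell is represented as a purely stoichiometric process network. Every
reaction is irreversible with bounds `0 ≤ lb ≤ ub` in µM·h⁻¹; where a
process is bidirectional it is written as a forward/backward pair. This
matches the data the model is built from — all flux ranges are
non-negative — and keeps the LP in a single orthant. Compartments
(cytosol, mitochondrion, vesicle, extracellular, lysosome) are metadata
only: no volume scaling enters the steady-state constraint. Reactions are
*not* elementally balanced; the network mixes genuine metabolites with
process species (damaged protein, damaged mitochondrion, αSYN aggregate),
so mass conservation is enforced per species, not per atom.

Boundary reactions follow the IN/OUT convention: inputs have only positive
stoichiometric coefficients, outputs only negative ones. The molecular
units of currency (O₂, H₂O, NAD⁺/NADH, Fe²⁺/Fe³⁺, ATP, ADP+Pi) have their
own exchange reactions and may flow in and out within their bounds.

## Bound policy

Bounds are assigned from a speed tag rather than stored ad hoc:

| tag | bounds (µM·h⁻¹) | meaning |
|---|---|---|
| `default` | (0, 100) | ordinary processes |
| `slow` | (0, 30) | processes known to be rare or slow |
| `best_et_al` | ref·(1 ± 0.10) | measured dopamine-pathway fluxes |

After the ±10 % window, the lower bounds of `OMSynthesis1`,
`OMSynthesis2`, `HVASynthesis3` and `HVASynthesis4` are forced to 0: the
whole-cell network offers additional routes for their substrates that the
original single-pathway kinetic study did not have, and keeping their
measured minimum would over-constrain the FBA. The policy is idempotent
and applied functionally (models are never mutated).

## FBA engine

`solve_fba` solves `max/min c·v s.t. S·v = 0, lb ≤ v ≤ ub` with scipy's
HiGHS backend. Because the reported tables print single flux values while
LP optima are routinely degenerate, a canonical secondary objective is
applied: with `c·v` fixed at the optimum, total flux `Σv` is minimized
(parsimonious solution). This makes output deterministic across runs and
solver versions; it does *not* make individual fluxes unique in every
case, so `flux_variability` computes per-reaction min/max at the fixed
optimum and anything with a range wider than 1e-6 is flagged non-unique.
Default tolerances: bound feasibility 1e-9, steady-state residual 1e-6,
FVA uniqueness 1e-6 (all configurable via `Tolerances`). Unboundedness
and infeasibility are reported as statuses, never clamped or raised.

`enumerate_vertices` is an independent oracle for instances of ≤ 12
reactions: every vertex of the flux polytope has at most rank(S)
reactions strictly between their bounds, so all subsets of "free"
reactions up to that size are enumerated, the non-free reactions take
every lb/ub combination, and the free block is solved by least squares
(residual tolerance 1e-8, bound tolerance 1e-9). The cap is hard — the
oracle refuses larger instances rather than approximating.

## The curated skeleton

`make_skeleton_model()` is a 56-reaction, 28-metabolite reconstruction
covering all eleven functional sub-systems of the cell and all 18
canonical flux groups. Its dopamine-pathway reference fluxes (tyrosine
hydroxylase 2.0, decarboxylase 2.0, COMT/MAO routes 10.0, vesicular
transport 1.0, release 1.0, re-uptake 0.1, extracellular clearance 0.8,
autoxidation 1.0 µM·h⁻¹) are curated choices on the scale of the original
kinetic measurements, fixed once so that (i) the basic model is feasible,
(ii) an obligatory dopamine-derived ROS flux exists under every
objective, and (iii) a zero-apoptosis steady state exists (the minApo
optimum is exactly 0). Mitochondrial repair, mitophagy and MPP⁺-driven
complex-I flux are tagged `slow`, which gives the neurotoxin scan a
finite non-apoptotic disposal capacity; basal αSYN influx is also `slow`
so that unconstrained maximization cannot saturate it. The same network
is shipped as `data/skeleton.tsv` (a test guards against drift between
the file and the code).

The skeleton is a *reconstruction*, not the deposited 139-reaction
network: group-level behavior is qualitatively comparable (constant DA
ROS production, apoptosis only under maxApo/minDeg, lysosome-dominated
maxDeg), but its absolute numbers and thresholds are its own. The
`provenance` field (`deposited` / `curated-skeleton` / `synthetic`)
records which network an analysis ran on.

## Experiments

* **Basic suite** — four independent solves (maxApo, minApo, maxDeg,
  minDeg), reported as group sums; the summed objective-group flux equals
  the LP optimum by construction, which is asserted in tests.
* **Input scans** — one input reaction is swept over a range (default
  step 1 µM·h⁻¹, the resolution at which thresholds are reported).
  `pin` mode (default) fixes lb = ub = value: two-sided effects such as a
  forced surplus only appear when the input is *pinned*, not merely
  allowed. `relax_ub` mode (ub = value only) is available and makes the
  optimum monotone in the scanned value, a property the tests exercise.
  The O₂ preset additionally puts weight 1 on the O₂ input inside the
  target function (`augment_objective`); with a pinned input this only
  shifts the objective by a constant but is kept as an explicit,
  recorded convention of that experiment.
* **Feasibility window** — smallest feasible scanned value and the end of
  the contiguous feasible run starting there. Infeasible points are data,
  not errors, so windows are always computable.
* **Onset** — `appears`: first scanned value whose group flux exceeds the
  tolerance (default 1e-6). `vanishes`: first value from which the flux
  stays below tolerance at *every* larger value; persistence protects the
  threshold against the transient solver fluctuations that narrow-banded
  models can show at high inputs. Infeasible points interrupt persistence
  runs and carry no flux.

Scan experiments are pure functions: the model object is unchanged and a
repeated run yields an identical result.

## Synthetic data

`generate_random_network` guarantees feasibility by *planting*: internal
stoichiometry is sampled sparsely with coefficients in ±{1, 2}, a planted
flux v* is drawn as dyadic rationals (multiples of 1/64 on [0, 10], so
every stoichiometric sum is exact in binary floating point and
|S·v*|∞ = 0 holds bit-for-bit), and boundary reactions are added whose
planted fluxes absorb each metabolite's net imbalance. Bounds are then
`lb = max(0, v*−slack), ub = v*+slack`; with slack 0 the network's unique
steady state is v* and any maximization optimum equals c·v* exactly.
Generation is a pure function of spec + seed and never calls a solver.

`generate_neuronlike_network` is a fixed ~27-reaction shape-mimic with
currency metabolites, all five apoptosis/degradation sink groups and a
designated input whose single obligatory consumer carries bounds (a, b)
derived from the seed — pinning that input is feasible iff a ≤ v ≤ b, so
a step-1 scan must recover the window exactly. A lysosomal bypass
guarantees a zero-apoptosis steady state. `micro_fixtures` adds
closed-form cases: capacity chain (optimum 10), diamond with free branch
split (FVA range (0, 10) per branch), an infeasible pinned input, and an
unbounded path.

What the generators do **not** emulate: biological stoichiometry beyond
sign structure, kinetic regulation, and the specific coupling patterns of
the real network. Green tests on synthetic instances therefore validate
the *engine and read-outs* (conservation, bounds, windows, onsets,
determinism), not biological conclusions.

## I/O conventions

SBML is read at Level 2 or 3; flux bounds are taken from fbc constructs
or legacy kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters, defaulting
to (0, 100) with a logged warning when absent. Species marked
`boundaryCondition` are dropped from the steady-state constraint rather
than given zero rows. Negative lower bounds are clamped to 0 (the
representation is strictly irreversible). Written SBML is Level 3
Version 1 with fbc bounds; package-specific fields (speed tag, reference
flux, groups, boundary kind, currency flag, full-precision bounds) travel
in a small custom annotation so write→read round trips are lossless and
byte-deterministic. The TSV dialect carries the same information in one
human-editable file. Cross-reference annotations of foreign files are
preserved verbatim but never interpreted.

## Problem sizes and runtime

The test suite and the acceptance script are desk-scale by design: oracle
sweeps use 100 networks of 8 reactions (about two seconds), scans use
step 1 over 0–100 (101 LPs) and 0–1000 for the energy experiment
(1001 LPs, a few seconds on the skeleton). The deposited-network checks
load a locally supplied SBML file and run in seconds to minutes.

## Known limitations

* Exact per-reaction agreement with any externally published flux table
  is contingent on alternate-optima handling; only objective values and
  FVA-unique fluxes are solver-independent. Non-unique reported fluxes
  are flagged rather than asserted.
* The skeleton's thresholds (MPTP onset 91, ATP window (0, 230), O₂
  lower edge 3 µM·h⁻¹ at default bounds) characterize the
  reconstruction, not the deposited network.
* The deposited network must be supplied as a local file; nothing is
  downloaded at run time.
* No kinetics: the engine finds steady-state flux distributions, not
  time courses, and the apoptosis groups model initiation only.
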