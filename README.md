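# dopafba

A constraint-based model of a whole dopaminergic nerve cell, with a
deterministic flux-balance-analysis engine and the in-silico experiment
suite used to probe it. It is aimed at systems-biology researchers who
want to study how a dopaminergic neuron balances dopamine handling,
oxidative stress, α-synuclein (αSYN) aggregation and its degradation
machinery — and under which conditions it is pushed into apoptosis, the
cell fate underlying Parkinson's disease.

## The model

The cell is a stoichiometric process network: metabolites and
irreversible reactions with finite flux bounds in µM·h⁻¹. A steady state
is a flux vector *v* with

```
S·v = 0,   lb ≤ v ≤ ub
```

where *S* is the metabolites × reactions stoichiometric matrix. Flux
balance analysis (FBA) optimizes a linear target function *c·v* over this
polytope. Four grouped target functions are built in: minimal/maximal
apoptosis (**minApo**/**maxApo**, over the Lewy-body- and
mitochondria-induced apoptosis-initiation reactions) and minimal/maximal
degradation (**minDeg**/**maxDeg**, over the lysosome, proteasome and
mitophagy routes). Because LP optima are generally non-unique, every
reported flux vector is canonicalized by a parsimonious tie-break
(minimize total flux at the fixed optimum), and flux variability analysis
(FVA) flags which reported fluxes are unique.

Bounds follow a uniform policy: ordinary reactions (0, 100) µM·h⁻¹, slow
reactions (0, 30), and the measured dopamine-pathway reactions ±10 %
around their reference flux (with four documented zero lower-bound
overrides: `OMSynthesis1/2`, `HVASynthesis3/4`).

The package ships a curated ~56-reaction skeleton reconstruction of the
cell (`make_skeleton_model()`) covering dopamine synthesis/metabolism/
transport, MPTP import and complex-I poisoning, ROS production and
damage, DJ-1 protection, αSYN aggregation and export, all three
degradation routes, mitochondrial quality control and currency-metabolite
exchange. The full deposited network (BioModels identifier
`MODEL1302200000`, 139 reactions / 111 metabolites) can be downloaded
manually and loaded with `read_sbml_model()`; the library itself performs
no network access.

## Worked example

```python
from dopafba import (make_skeleton_model, skeleton_groups,
                     run_objective_suite, run_scan, find_onset, ScanSpec)

model = make_skeleton_model()
groups = skeleton_groups()

suite = run_objective_suite(model, groups)
print(suite.to_frame().round(2))

scan = run_scan(model, ScanSpec.sweep("MPTP_IN", stop=100,
                                      objective_label="maxDeg"), groups)
print(find_onset(scan, "Apoptosis (mitochondria)", "appears").threshold)
```

The suite prints the group × objective flux grid (µM·h⁻¹), e.g.

```
                       maxApo  minApo  maxDeg  minDeg
ROS production (DA)      0.90    0.90    0.90    0.90
Apoptosis (LBs)         30.00    0.00    0.00    0.90
Apoptosis (mitochondria) 84.16   0.00    0.00    0.00
Degradation (lysosome)   0.00    0.00   76.10    0.00
```

— the obligatory dopamine-autoxidation ROS flux (0.90) is present under
every objective; a healthy cell admits a completely apoptosis-free steady
state (minApo column), while maximal degradation routes damaged material
through the lysosome. The scan prints `91.0`: below an MPTP exposure of
91 µM·h⁻¹ the repair, mitophagy and complex-I routes absorb the toxin,
and from 91 on cytochrome-C release — mitochondria-induced apoptosis —
becomes unavoidable.

The `examples/` directory holds one short script per capability (basic
suite, neurotoxin scan, energy window, synthetic-network oracle, model
exchange). A thin CLI wraps the same functions:

```
dopafba validate src/dopafba/data/skeleton.tsv
dopafba run --model src/dopafba/data/skeleton.tsv --experiment mptp --out out/
dopafba simulate --seed 42 --out out/
```

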