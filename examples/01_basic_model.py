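"""Normal-cell baseline: the four-objective flux table.

Builds the curated dopaminergic-neuron skeleton and solves it under the
four canonical target functions (maximal/minimal apoptosis, maximal/
minimal degradation).  The printed grid gives each biological flux group's
summed flux in µM·h⁻¹ under each objective: a healthy cell shows zero
apoptosis under minApo, while maxDeg routes material through the lysosome.
"""

from dopafba import make_skeleton_model, run_objective_suite, skeleton_groups

model = make_skeleton_model()
groups = skeleton_groups()
print(f"model: {len(model.metabolites)} metabolites, "
      f"{len(model.reactions)} reactions ({model.provenance})")

suite = run_objective_suite(model, groups)
print(suite.to_frame().round(2).to_string())
print("\nobjective optima (µM·h⁻¹):",
      {k: round(v, 2) for k, v in suite.objective_values.items()})
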