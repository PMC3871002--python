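"""Neurotoxin challenge: MPTP input scan with apoptosis-onset detection.

Pins the MPTP exposure flux at 0, 1, ..., 100 µM·h⁻¹ and re-solves the
model under maximal degradation at every value.  While repair, mitophagy
and the complex-I route can absorb the toxin load, apoptosis stays at
zero; the printed onset is the first exposure at which cytochrome-C
release (mitochondria-induced apoptosis initiation) becomes unavoidable.
"""

from dopafba import (
    ScanSpec, find_onset, make_skeleton_model, run_scan, skeleton_groups,
)

model = make_skeleton_model()
groups = skeleton_groups()
scan = run_scan(model, ScanSpec.sweep("MPTP_IN", stop=100,
                                      objective_label="maxDeg"), groups)

onset = find_onset(scan, "Apoptosis (mitochondria)", "appears")
print(f"mitochondria-induced apoptosis starts at MPTP input "
      f"{onset.threshold:g} µM·h⁻¹")
for value in (80, 90, 95, 100):
    p = scan.points[value]
    print(f"  MPTP {value:>3}: apoptosis (mito) = "
          f"{p.group_fluxes['Apoptosis (mitochondria)']:.2f}, "
          f"mitophagy = {p.group_fluxes['Degradation (mitophagy)']:.2f}")
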