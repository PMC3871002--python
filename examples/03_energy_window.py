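"""Energy supply: the feasible ATPase window.

Pins the ATP input flux from 0 to 1000 µM·h⁻¹ (step 1) under maximal
degradation.  Beyond the window's upper edge the cell cannot dispose of
the pinned ATP surplus through export and ATP-consuming processes, and no
steady state exists.
"""

from dopafba import (
    ScanSpec, find_feasibility_window, make_skeleton_model, run_scan,
    skeleton_groups,
)

model = make_skeleton_model()
groups = skeleton_groups()
scan = run_scan(model, ScanSpec.sweep("ATP_IN", stop=1000,
                                      objective_label="maxDeg"), groups)
w = find_feasibility_window(scan)
print(f"feasible ATPase input window: {w.min_feasible:g} to "
      f"{w.max_feasible:g} µM·h⁻¹")
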