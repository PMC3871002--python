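{
  "experiment": "atp",
  "description": "Energy supply sweep: the ATPase input flux is pinned from 0 to 1000 uM/h to find the feasible energy window.",
  "input_reaction": "ATP_IN",
  "start": 0,
  "stop": 1000,
  "step": 1,
  "objectives": ["minApo", "maxDeg"],
  "pin_mode": "pin",
  "augment_objective": false,
  "onset_groups": ["Apoptosis (LBs)", "Apoptosis (mitochondria)"]
}
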