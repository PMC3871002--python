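{
  "experiment": "o2",
  "description": "Oxygen availability sweep. The O2 input reaction is additionally included in the target function with weight 1 in the primary sense.",
  "input_reaction": "O2_IN",
  "start": 0,
  "stop": 100,
  "step": 1,
  "objectives": ["minApo", "maxDeg"],
  "pin_mode": "pin",
  "augment_objective": true,
  "onset_groups": ["Apoptosis (LBs)", "Apoptosis (mitochondria)"]
}
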