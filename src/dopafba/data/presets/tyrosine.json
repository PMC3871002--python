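{
  "experiment": "tyrosine",
  "description": "Dopamine-synthesis precursor sweep: the tyrosine input flux pinned from 0 to 100 uM/h.",
  "input_reaction": "TYR_IN",
  "start": 0,
  "stop": 100,
  "step": 1,
  "objectives": ["minApo", "maxDeg"],
  "pin_mode": "pin",
  "augment_objective": false,
  "onset_groups": ["Apoptosis (LBs)", "Apoptosis (mitochondria)", "ROS production (DA)"]
}
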