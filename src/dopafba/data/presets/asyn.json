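{
  "experiment": "asyn",
  "description": "alpha-synuclein load sweep: the aSYN input flux pinned from 0 to 100 uM/h; aggregation, export and apoptosis are the read-outs.",
  "input_reaction": "ASYN_IN",
  "start": 0,
  "stop": 100,
  "step": 1,
  "objectives": ["minApo", "maxDeg"],
  "pin_mode": "pin",
  "augment_objective": false,
  "onset_groups": ["aSYN aggregation", "aSYN output reaction", "Apoptosis (LBs)", "Apoptosis (mitochondria)"]
}
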