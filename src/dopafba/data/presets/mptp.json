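{
  "experiment": "mptp",
  "description": "Neurotoxin sweep: MPTP exposure pinned from 0 to 100 uM/h; apoptosis onset is the headline read-out.",
  "input_reaction": "MPTP_IN",
  "start": 0,
  "stop": 100,
  "step": 1,
  "objectives": ["minApo", "maxDeg"],
  "pin_mode": "pin",
  "augment_objective": false,
  "onset_groups": ["Apoptosis (mitochondria)", "Apoptosis (LBs)"]
}
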