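{
  "experiment": "basic",
  "description": "Normal nerve cell: four target functions (maxApo, minApo, maxDeg, minDeg) on the unmodified model; reported as the group-by-objective flux grid."
}
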