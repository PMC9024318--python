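# Default 10-encode multi-PLD multi-b DW-ASL protocol.
# Five crushed b=20 encodes across PLDs (NEX=3), then a multi-b block at
# PLD=1200 ms (NEX=1). Encodes with b >= b_crush are capillary-crushed.
delta_s: 1.5
epsilon: 0.6
lambda_ml_per_g: 0.9
r1a_per_s: 0.6
b_crush: 10.0
encodes:
  - {pld_ms: 1000, b: 20, nex: 3}
  - {pld_ms: 1500, b: 20, nex: 3}
  - {pld_ms: 1800, b: 20, nex: 3}
  - {pld_ms: 2000, b: 20, nex: 3}
  - {pld_ms: 2500, b: 20, nex: 3}
  - {pld_ms: 1200, b: 0, nex: 1}
  - {pld_ms: 1200, b: 10, nex: 1}
  - {pld_ms: 1200, b: 20, nex: 1}
  - {pld_ms: 1200, b: 50, nex: 1}
  - {pld_ms: 1200, b: 100, nex: 1}
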