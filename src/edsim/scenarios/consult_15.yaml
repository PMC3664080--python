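# Sensitivity: consultation time increased to a 15-minute mean
# (the baseline consult mean differs between the inputs table, 4.5 min,
# and the sensitivity row's "5 to 15 minutes"; both stay configurable)
label: consult_15
seed: 106
overrides:
  services:
    consult:
      family: triangular
      mean: 15.0
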