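# Sensitivity: number of beds doubled from 5 to 10
label: beds_10
seed: 103
overrides:
  beds: 10
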