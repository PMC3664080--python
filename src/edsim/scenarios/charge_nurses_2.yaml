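# Sensitivity: charge nurses increased from 1 to 2
label: charge_nurses_2
seed: 104
overrides:
  charge_nurses: 2
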