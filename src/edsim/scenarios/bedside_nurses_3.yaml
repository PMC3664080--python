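# Sensitivity: bedside nurses increased from 2 to 3
label: bedside_nurses_3
seed: 105
overrides:
  bedside_nurses: 3
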