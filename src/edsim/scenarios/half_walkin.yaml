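# Sensitivity: walk-in arrival rate halved (ambulance arrivals unchanged)
label: half_walkin
seed: 102
overrides:
  walk_in_multiplier: 0.5
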