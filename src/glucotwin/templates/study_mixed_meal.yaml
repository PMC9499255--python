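scheme: custom
horizon_days: 0.5
meals:
- start_h: 1.0
  carb_g: 87.0
  protein_g: 23.0
  fat_g: 20.0
  duration_min: 15.0
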