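scheme: SFM
horizon_days: 7.0
meals:
- start_h: 8.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 13.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 19.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 32.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 37.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 43.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 56.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 61.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 67.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 80.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 85.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 91.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 104.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 109.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 115.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 128.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 133.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 139.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 152.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 157.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
- start_h: 163.0
  carb_g: 75.7576
  protein_g: 45.4545
  fat_g: 20.202
  duration_min: 15.0
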