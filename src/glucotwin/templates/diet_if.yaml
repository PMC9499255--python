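scheme: IF
horizon_days: 7.0
meals:
- start_h: 12.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 20.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 36.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 44.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 60.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 68.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 84.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 92.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 108.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 116.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 132.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 140.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 156.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
- start_h: 164.0
  carb_g: 113.6364
  protein_g: 68.1818
  fat_g: 30.303
  duration_min: 15.0
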