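{
  "r_s_ohm": 4613.0,
  "c_dl_uF_per_cm2": 7.41,
  "alpha": 0.868,
  "c_q_uF_per_cm2": 3.72,
  "r_ct_ohm": 1360000.0,
  "w_mag_ohm_s_neg_half": 640000000.0,
  "b_s_half": 0.703,
  "area_cm2": 0.0001,
  "roughness": 1.07
}
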