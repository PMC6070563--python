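{
 "schema": 1,
 "mode": "dox",
 "description": "MRC5-like fibroblast preset: reference model time-rescaled so the TNC 2-fold induction delay at dox level 1.0 is 8 days.",
 "dox_level": 1.0,
 "bistable_stimulus": 0.5,
 "parameters": {
  "basal_Tw": 0.00023426593945263154,
  "basal_P": 0.00023426593945263154,
  "basal_T": 0.00023426593945263154,
  "vmax_dox": 2.342659394526315,
  "km_dox": 1.0,
  "n_dox": 1.0,
  "v_feedback": 8.199307880842102,
  "km_feedback": 5.0,
  "n_feedback": 1.0,
  "vmax_TwP": 1.1713296972631575,
  "km_TwP": 15.0,
  "n_TwP": 2.0,
  "vmax_PT": 1.1713296972631575,
  "km_PT": 8.0,
  "n_PT": 2.0,
  "deg_Tw": 0.23426593945263152,
  "deg_P": 0.11713296972631576,
  "deg_T": 0.11713296972631576
 }
}
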