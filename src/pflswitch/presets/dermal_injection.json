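{
 "schema": 1,
 "mode": "tnc_injection",
 "description": "Dermal-fibroblast exogenous-TNC injection model at the irreversible anchor (km_feedback, v_feedback) = (5, 30); reversible at (10, 15). 1 ug of exogenous TNC maps to 1 a.u. of stimulus.",
 "dose_scale": 1.0,
 "parameters": {
  "basal_Tw": 2.0,
  "basal_P": 0.3,
  "basal_T": 0.3,
  "vmax_dox": 0.0,
  "km_dox": 1.0,
  "n_dox": 1.0,
  "v_feedback": 30.0,
  "km_feedback": 5.0,
  "n_feedback": 4.0,
  "vmax_TwP": 6.0,
  "km_TwP": 10.0,
  "n_TwP": 4.0,
  "vmax_PT": 8.0,
  "km_PT": 4.0,
  "n_PT": 4.0,
  "deg_Tw": 1.0,
  "deg_P": 1.0,
  "deg_T": 1.0
 }
}
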