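{
 "schema": 1,
 "mode": "dox",
 "description": "Reference dox-induction model: bistable and reversible at the default feedback strength, irreversible at v_feedback >= ~42.",
 "dox_level": 1.0,
 "bistable_stimulus": 0.5,
 "parameters": {
  "basal_Tw": 0.001,
  "basal_P": 0.001,
  "basal_T": 0.001,
  "vmax_dox": 10.0,
  "km_dox": 1.0,
  "n_dox": 1.0,
  "v_feedback": 35.0,
  "km_feedback": 5.0,
  "n_feedback": 1.0,
  "vmax_TwP": 5.0,
  "km_TwP": 15.0,
  "n_TwP": 2.0,
  "vmax_PT": 5.0,
  "km_PT": 8.0,
  "n_PT": 2.0,
  "deg_Tw": 1.0,
  "deg_P": 0.5,
  "deg_T": 0.5
 }
}
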