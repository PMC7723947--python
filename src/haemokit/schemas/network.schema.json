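{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "haemokit aortic network",
 "type": "object",
 "required": ["branches"],
 "properties": {
  "venous_pressure_mmHg": {"type": "number", "default": 0},
  "branches": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["label", "R1_mmHg_s_per_mL", "R2_mmHg_s_per_mL", "C_mL_per_mmHg"],
    "properties": {
     "label": {"type": "string"},
     "R1_mmHg_s_per_mL": {"type": "number", "exclusiveMinimum": 0},
     "R2_mmHg_s_per_mL": {"type": "number", "exclusiveMinimum": 0},
     "C_mL_per_mmHg": {"type": "number", "exclusiveMinimum": 0},
     "R_series_mmHg_s_per_mL": {"type": "number", "minimum": 0, "default": 0}
    }
   }
  }
 }
}
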