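{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "haemokit calibration target set",
 "type": "object",
 "required": ["P_sys_mmHg", "P_dia_mmHg", "Q_inlet_mL_per_s", "branch_flows_mL_per_s"],
 "properties": {
  "P_sys_mmHg": {"type": "number", "exclusiveMinimum": 0},
  "P_dia_mmHg": {"type": "number", "exclusiveMinimum": 0},
  "Q_inlet_mL_per_s": {"type": "number", "exclusiveMinimum": 0},
  "branch_flows_mL_per_s": {
   "type": "object",
   "minProperties": 1,
   "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
  }
 }
}
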