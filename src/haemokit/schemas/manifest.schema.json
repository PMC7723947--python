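{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "haemokit field-ensemble manifest",
 "type": "object",
 "required": ["frame_rate_hz", "period_s", "frames_per_cycle", "n_cycles", "grid_shape", "frames"],
 "properties": {
  "frame_rate_hz": {"type": "number", "exclusiveMinimum": 0},
  "period_s": {"type": "number", "exclusiveMinimum": 0},
  "frames_per_cycle": {"type": "integer", "minimum": 1},
  "n_cycles": {"type": "integer", "minimum": 1},
  "grid_shape": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2},
  "frames": {"type": "array", "items": {"type": "string"}}
 },
 "description": "frames length must equal frames_per_cycle * n_cycles; frame CSVs have columns x_m,y_m,u_mps,v_mps,valid"
}
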