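{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "imepmap run report",
 "type": "object",
 "required": ["version", "seed", "config_hash", "stages", "tasks",
              "incomplete"],
 "properties": {
  "version": {"type": "string"},
  "seed": {"type": "integer"},
  "config_hash": {"type": "string"},
  "incomplete": {"type": "boolean"},
  "stages": {
   "type": "object",
   "additionalProperties": {
    "type": "object",
    "required": ["seconds"],
    "properties": {"seconds": {"type": "number"}}
   }
  },
  "tasks": {
   "type": "object",
   "additionalProperties": {
    "type": "object",
    "required": ["status"],
    "properties": {
     "status": {"enum": ["ok", "no_response"]},
     "n_participants": {"type": "integer"},
     "group_cog": {"type": "array", "items": {"type": "number"},
                   "minItems": 3, "maxItems": 3},
     "mean_shift_mm": {"type": "array", "items": {"type": "number"},
                       "minItems": 3, "maxItems": 3},
     "comparison": {
      "type": "object",
      "additionalProperties": {
       "type": "object",
       "required": ["mean_diff", "hdi_low", "hdi_high", "accuracy",
                    "tier", "rhat", "ess_delta", "converged"]
      }
     }
    }
   }
  },
  "task_model": {"type": "object"},
  "task_areas": {"type": "array"},
  "levene": {"type": "object"},
  "no_response": {"type": "array"}
 }
}
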