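{
  "required": {
    "occupancy": "object",
    "pmf": "object",
    "comparison": {
      "type": "object",
      "required": {
        "definition_of_total": "string",
        "totals_a": "object",
        "totals_b": "object",
        "differences": "object",
        "mean_difference_kcal_mol": "number",
        "ci_low": "number_or_null",
        "ci_high": "number_or_null"
      }
    },
    "provenance": {
      "type": "object",
      "required": {
        "package": "string",
        "version": "string",
        "master_seed": "integer",
        "temperature_K": "number",
        "kT_kcal_mol": "number",
        "planned_monitoring_frames": "integer",
        "config": "object",
        "artifacts": "object"
      }
    }
  }
}
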