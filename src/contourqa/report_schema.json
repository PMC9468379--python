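{
  "type": "object",
  "required": ["toolkit", "n_rows", "cohort_columns", "comparisons"],
  "properties": {
    "toolkit": {"type": "string"},
    "n_rows": {"type": "integer"},
    "cohort_columns": {"type": "array", "items": {"type": "string"}},
    "comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["metric", "ks_statistic", "p_value"],
        "properties": {
          "metric": {"type": "string"},
          "ks_statistic": {"type": "number"},
          "p_value": {"type": "number"},
          "pass_mean": {"type": "number"},
          "pass_sd": {"type": "number"},
          "fail_mean": {"type": "number"},
          "fail_sd": {"type": "number"},
          "n_pass": {"type": "integer"},
          "n_fail": {"type": "integer"}
        }
      }
    }
  }
}
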