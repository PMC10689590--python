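{
  "site": "Bern",
  "v_d": 0.55,
  "recovery_late": 0.836,
  "auc_vs_ca": {"slope": 104.0, "intercept": 2.9},
  "theta_vs_lambda3": {"slope": 2971.0, "intercept": 72.89},
  "theta_vs_age": {"slope": 0.0477, "intercept": 98.0},
  "lambda3_vs_age": {"slope": 0.0, "intercept": 0.00946},
  "units_note": "bern-raw-kBq-mL",
  "schema_version": 1
}
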