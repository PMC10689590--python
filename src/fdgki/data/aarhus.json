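{
  "site": "Aarhus",
  "v_d": 0.55,
  "recovery_late": 0.847,
  "auc_vs_ca": {"slope": 63.2, "intercept": 374.0},
  "theta_vs_lambda3": {"slope": 2953.0, "intercept": 75.57},
  "theta_vs_age": {"slope": -0.313, "intercept": 129.0},
  "lambda3_vs_age": {"slope": -9.36e-05, "intercept": 0.0174},
  "units_note": "aarhus-raw-kBq-mL",
  "schema_version": 1
}
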