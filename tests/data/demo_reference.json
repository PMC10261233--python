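{
  "calibration_alpha": 3.378210958090812,
  "calibration_delta": 8.078715526789237,
  "calibration_rss": 3.944304526105059e-30,
  "condition": "rest",
  "demo_seed": 20,
  "eval_bland_altman_a": 80.25535925938789,
  "eval_bland_altman_b": -17653.5,
  "eval_condition": "rest",
  "eval_delta_r_all_pct": 174.79319119587913,
  "eval_delta_r_concordant_pct": 162.18978679381874,
  "eval_f1": 0.8,
  "eval_kappa_ci_high": 0.4944381756183488,
  "eval_kappa_ci_low": 0.057285962312685346,
  "eval_kappa_lw": 0.27586206896551707,
  "eval_n_pairs": 6,
  "eval_sensitivity": 0.6666666666666666,
  "eval_specificity": null,
  "n_test": 6,
  "n_train": 6,
  "per_case_csct_pseudomass": [
    2374.5,
    36772.5,
    1692.0,
    19302.0,
    25755.0,
    31917.0
  ],
  "per_case_ctac_pseudomass": [
    0.0,
    1108.5,
    0.0,
    1227.0,
    5755.5,
    3801.0
  ],
  "per_case_true_pseudomass": [
    2329.2000000000003,
    32412.800000000007,
    640.4000000000001,
    17828.000000000004,
    23469.600000000006,
    27790.800000000007
  ],
  "provenance_config_hash": "6f76dba980dd4b09"
}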