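{
  "version": 1,
  "per_afferent": [
    "afferent_id",
    "organ",
    "regularity",
    "condition",
    "cv",
    "cv_star",
    "class_label",
    "mean_rate",
    "modulation",
    "p_zero",
    "resting_discharge",
    "linear_b",
    "linear_coef1",
    "linear_coef2",
    "lead_s",
    "gain_st",
    "vaf_linear",
    "ln_st",
    "ln_r0",
    "ln_c1",
    "ln_c2",
    "ln_c3",
    "ln_bias",
    "ln_modulation",
    "vaf_ln"
  ],
  "class_summary": [
    "organ",
    "regularity",
    "condition",
    "n",
    "mean_rate",
    "modulation",
    "p_zero",
    "vaf_linear",
    "vaf_ln",
    "ln_bias",
    "ln_modulation"
  ],
  "contrasts": [
    "name",
    "organ",
    "regularity",
    "metric",
    "statistic",
    "p_value",
    "slope",
    "ci_low",
    "ci_high"
  ]
}
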