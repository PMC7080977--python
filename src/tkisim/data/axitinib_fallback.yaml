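# Fallback parameter set (axitinib): documented round-number values with the
# same schema as the reference set; for structural testing and demos.
drug: axitinib
fixed_effects:
  ka: 0.5
  cl: 10.0
  v: 50.0
  wt_ref: 70.0
  wt_exp_cl: 0.75
  wt_exp_v: 1.0
  base_svegfr3: 60.0
  mrt_svegfr3_h: 100.0
  imax_svegfr3: 1.0
  ic50_svegfr3: 10.0
  base_dbp: 80.0
  mrt_dbp_h: 100.0
  emax_dbp: 0.3
  ec50_dbp: 10.0
  tum_kg: 0.0001
  tum_kv3: 0.0004
  tum_lambda_res: 0.0001
  tum_tmax: 1000.0
  os_weib_scale_h: 99999.99999999999
  os_weib_shape: 1.0
  os_beta_sld: 0.3
  os_beta_prog: 0.7
  drop_lambda_h: 2.0e-05
  drop_beta_prog: 0.7
  drop_beta_sld: 0.1
  drop_beta_auc: 0.2
iiv:
  cl: 0.2
  v: 0.3
  ka: 0.5
  base_svegfr3: 0.06
  ic50_svegfr3: 0.2
  base_dbp: 0.01
  emax_dbp: 0.2
  mrt_dbp_h: 0.2
  tum_kg: 0.2
  tum_kv3: 0.2
residual_errors:
  conc:
    proportional: 0.3
    additive: 0.0
  svegfr3:
    proportional: 0.2
    additive: 0.0
  dbp:
    proportional: 0.05
    additive: 3.0
provenance:
  ka: fallback round-number value
  cl: fallback round-number value
  v: fallback round-number value
  wt_ref: fallback round-number value
  wt_exp_cl: fallback round-number value
  wt_exp_v: fallback round-number value
  base_svegfr3: fallback round-number value
  mrt_svegfr3_h: fallback round-number value
  imax_svegfr3: fallback round-number value
  ic50_svegfr3: fallback round-number value
  base_dbp: fallback round-number value
  mrt_dbp_h: fallback round-number value
  emax_dbp: fallback round-number value
  ec50_dbp: fallback round-number value
  tum_kg: fallback round-number value
  tum_kv3: fallback round-number value
  tum_lambda_res: fallback round-number value
  tum_tmax: fallback round-number value
  os_weib_scale_h: fallback round-number value
  os_weib_shape: fallback round-number value
  os_beta_sld: fallback round-number value
  os_beta_prog: fallback round-number value
  drop_lambda_h: fallback round-number value
  drop_beta_prog: fallback round-number value
  drop_beta_sld: fallback round-number value
  drop_beta_auc: fallback round-number value
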