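# Fallback parameter set (sunitinib): documented round-number values with the
# same schema as the reference set; for structural testing and demos.
drug: sunitinib
fixed_effects:
  ka: 0.2
  cl_parent: 50.0
  v_parent: 2000.0
  fm: 0.2
  cl_met: 30.0
  v_met: 3000.0
  wt_ref: 70.0
  wt_exp_cl: 0.75
  wt_exp_v: 1.0
  base_svegfr3: 60.0
  mrt_svegfr3_h: 100.0
  imax_svegfr3: 1.0
  ic50_svegfr3: 80.0
  base_skit: 40.0
  mrt_skit_h: 1000.0
  imax_skit: 1.0
  ic50_skit: 20.0
  base_anc: 5.0
  mtt_anc_h: 100.0
  gamma_anc: 0.2
  slope_anc: 0.2
  base_plt: 200.0
  mtt_plt_h: 100.0
  gamma_plt: 0.2
  emax_plt: 0.2
  auc50_plt: 1000.0
  base_dbp: 80.0
  mrt_dbp_h: 100.0
  slope_dbp: 7.0e-05
  fat_int_g1: -5.0
  fat_int_g2: -10.0
  fat_int_g3: -10.0
  fat_beta_v3: 2.0
  fat_kappa: 2.0
  hfs_int_g1: -5.0
  hfs_int_g2: -10.0
  hfs_int_g3: -10.0
  hfs_beta_v3: 3.0
  hfs_kappa: 3.0
  tum_kg: 0.0002
  tum_kv3: 0.0006
  tum_kskit: 0.0001
  tum_kauc_max: 0.0003
  tum_auc50: 1000.0
  tum_lambda_res: 0.0001
  tum_tmax: 1000.0
  os_tad_weib_scale_h: 9000.0
  os_tad_weib_shape: 1.0
  os_tad_beta_dbp: -3.0
  os_tad_beta_anc: 3.0
  os_tad_beta_bsld: 0.004
  os_bad_weib_scale_h: 10000.0
  os_bad_weib_shape: 1.0
  os_bad_beta_v3: 2.0
  os_bad_beta_bsld: 0.004
  bsld_ref: 182.7
  drop_lambda_h: 2.0e-05
  drop_beta_prog: 0.7
  drop_beta_sld: 0.1
iiv:
  cl_parent: 0.2
  v_parent: 0.1
  ka: 0.3
  cl_met: 0.1
  base_svegfr3: 0.06
  ic50_svegfr3: 0.2
  base_skit: 0.05
  ic50_skit: 0.2
  base_anc: 0.05
  slope_anc: 0.2
  mtt_anc_h: 0.03
  base_plt: 0.06
  emax_plt: 0.2
  base_dbp: 0.01
  slope_dbp: 0.2
  tum_kg: 0.2
  tum_kv3: 0.2
residual_errors:
  conc:
    proportional: 0.3
    additive: 0.0
  svegfr3:
    proportional: 0.2
    additive: 0.0
  skit:
    proportional: 0.2
    additive: 0.0
  anc:
    proportional: 0.3
    additive: 0.0
  platelets:
    proportional: 0.2
    additive: 0.0
  dbp:
    proportional: 0.06
    additive: 0.0
provenance:
  ka: fallback round-number value
  cl_parent: fallback round-number value
  v_parent: fallback round-number value
  fm: fallback round-number value
  cl_met: fallback round-number value
  v_met: fallback round-number value
  wt_ref: fallback round-number value
  wt_exp_cl: fallback round-number value
  wt_exp_v: fallback round-number value
  base_svegfr3: fallback round-number value
  mrt_svegfr3_h: fallback round-number value
  imax_svegfr3: fallback round-number value
  ic50_svegfr3: fallback round-number value
  base_skit: fallback round-number value
  mrt_skit_h: fallback round-number value
  imax_skit: fallback round-number value
  ic50_skit: fallback round-number value
  base_anc: fallback round-number value
  mtt_anc_h: fallback round-number value
  gamma_anc: fallback round-number value
  slope_anc: fallback round-number value
  base_plt: fallback round-number value
  mtt_plt_h: fallback round-number value
  gamma_plt: fallback round-number value
  emax_plt: fallback round-number value
  auc50_plt: fallback round-number value
  base_dbp: fallback round-number value
  mrt_dbp_h: fallback round-number value
  slope_dbp: fallback round-number value
  fat_int_g1: fallback round-number value
  fat_int_g2: fallback round-number value
  fat_int_g3: fallback round-number value
  fat_beta_v3: fallback round-number value
  fat_kappa: fallback round-number value
  hfs_int_g1: fallback round-number value
  hfs_int_g2: fallback round-number value
  hfs_int_g3: fallback round-number value
  hfs_beta_v3: fallback round-number value
  hfs_kappa: fallback round-number value
  tum_kg: fallback round-number value
  tum_kv3: fallback round-number value
  tum_kskit: fallback round-number value
  tum_kauc_max: fallback round-number value
  tum_auc50: fallback round-number value
  tum_lambda_res: fallback round-number value
  tum_tmax: fallback round-number value
  os_tad_weib_scale_h: fallback round-number value
  os_tad_weib_shape: fallback round-number value
  os_tad_beta_dbp: fallback round-number value
  os_tad_beta_anc: fallback round-number value
  os_tad_beta_bsld: fallback round-number value
  os_bad_weib_scale_h: fallback round-number value
  os_bad_weib_shape: fallback round-number value
  os_bad_beta_v3: fallback round-number value
  os_bad_beta_bsld: fallback round-number value
  bsld_ref: fallback round-number value
  drop_lambda_h: fallback round-number value
  drop_beta_prog: fallback round-number value
  drop_beta_sld: fallback round-number value
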