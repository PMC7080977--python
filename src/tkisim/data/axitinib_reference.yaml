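# Reference parameter set for the axitinib/mRCC simulation framework.
# Units convention as in sunitinib_reference.yaml.

drug: axitinib

fixed_effects:
  # --- PK: 1-cpt, 1st-order absorption (XLI oral formulation)
  ka: 0.482            # 1/h
  cl: 14.6             # L/h apparent
  v: 47.3              # L
  wt_ref: 70.0
  wt_exp_cl: 0.75
  wt_exp_v: 1.0
  # --- sVEGFR-3: indirect response, Imax inhibition by axitinib conc
  base_svegfr3: 63.9   # ng/ml
  mrt_svegfr3_h: 100.0
  imax_svegfr3: 1.0
  ic50_svegfr3: 10.0
  # --- Diastolic BP: indirect response, Emax stimulation of k_in
  base_dbp: 78.0       # mmHg
  mrt_dbp_h: 96.0
  emax_dbp: 0.30       # maximal fractional k_in stimulation
  ec50_dbp: 10.0       # ng/ml
  # --- Tumor growth inhibition, sVEGFR-3-driven
  tum_kg: 1.5e-4       # 1/h
  tum_kv3: 4.0e-4      # kill per unit rel. sVEGFR-3 decrease, 1/h
  tum_lambda_res: 1.2e-4
  tum_tmax: 1200.0     # mm carrying capacity
  # --- OS: Weibull baseline, driven by current SLD and progression status
  os_weib_scale_h: 108000.0
  os_weib_shape: 1.2
  os_beta_sld: 0.3     # per 100 mm current SLD
  os_beta_prog: 0.7    # progression indicator
  # --- Dropout: exponential baseline, exposure + progression + size
  drop_lambda_h: 2.0e-5
  drop_beta_prog: 0.7
  drop_beta_sld: 0.1   # per 100 mm current SLD
  drop_beta_auc: 0.2   # per (ug*h/ml) daily AUC

iiv:
  cl: 0.25
  v: 0.28
  ka: 0.50
  base_svegfr3: 0.06
  ic50_svegfr3: 0.25
  base_dbp: 0.01
  emax_dbp: 0.25
  mrt_dbp_h: 0.20
  tum_kg: 0.15
  tum_kv3: 0.20

residual_errors:
  conc:    {proportional: 0.30, additive: 0.0}
  svegfr3: {proportional: 0.20, additive: 0.0}
  # combined additive + proportional residual error for axitinib dBP
  dbp:     {proportional: 0.05, additive: 3.0}

provenance:
  ka: "structure/magnitude after Garrett et al. axitinib popPK"
  cl: "after Garrett et al."
  v: "after Garrett et al."
  wt_ref: "package allometry convention"
  wt_exp_cl: "standard allometric exponent"
  wt_exp_v: "standard allometric exponent"
  base_svegfr3: "representative, same assay scale as sunitinib framework"
  mrt_svegfr3_h: "representative"
  imax_svegfr3: "full inhibition assumed"
  ic50_svegfr3: "representative, typical 5 mg b.i.d. suppression ~70%"
  base_dbp: "representative normotensive baseline"
  mrt_dbp_h: "representative BP turnover"
  emax_dbp: "Emax exposure-dBP structure after Chen et al. 2015"
  ec50_dbp: "after Chen et al. 2015, representative"
  tum_kg: "TGI structure after Claret et al. 2009; representative mRCC growth"
  tum_kv3: "representative"
  tum_lambda_res: "representative resistance kinetics"
  tum_tmax: "saturating growth, representative maximal tumor burden"
  os_weib_scale_h: "design-time calibration, see docs/methods.md"
  os_weib_shape: "design-time calibration"
  os_beta_sld: "tumor burden raises hazard"
  os_beta_prog: "progression raises hazard"
  drop_lambda_h: "representative background discontinuation"
  drop_beta_prog: "progression raises dropout"
  drop_beta_sld: "tumor burden raises dropout"
  drop_beta_auc: "exposure (toxicity burden) raises dropout"
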