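# Utility-value table for QALY computation (EQ-5D scale, 0 = death,
# 1 = perfect health). Daily utility = baseline x disease-status factor x
# product of the five AE factors at that day's grades (multiplicative model).
# Values are representative literature-style placeholders; pure config.

baseline: 0.78

disease_status:
  stable: 1.0
  progressed: 0.82

# Multiplicative factor per AE by grade 0..4 (grade 0 -> 1.0, no decrement).
ae_factors:
  neutropenia:      [1.0, 1.0, 0.99, 0.91, 0.85]
  thrombocytopenia: [1.0, 1.0, 0.99, 0.93, 0.88]
  hypertension:     [1.0, 0.99, 0.97, 0.94, 0.90]
  fatigue:          [1.0, 0.96, 0.88, 0.80, 0.80]
  hfs:              [1.0, 0.96, 0.90, 0.84, 0.84]
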