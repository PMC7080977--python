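# Cost configuration for the sunitinib cost-effectiveness analysis (EUR).
# Drug capsule prices and follow-up tariffs are placeholders to be filled from
# the Dutch NZa / Zorginstituut tariff databases; AE management costs are
# placeholders for the German per-event cost compilation. All values are pure
# config inputs -- the analysis code never assumes particular numbers.

capsule_prices:       # EUR per capsule, by strength (mg)
  12.5: 40.66
  25.0: 81.31
  37.5: 121.97
  50.0: 162.62

followup:
  visit: 91.0         # EUR per monitoring visit (medical consult)
  lab_panel: 45.0     # EUR per laboratory investigation
  radiology: 180.0    # EUR per imaging assessment (every 12 weeks)

# Per-event AE management cost by CTCAE grade (EUR); grade index 0..4.
ae_event_costs:
  neutropenia:      [0.0, 0.0, 120.0, 1500.0, 3000.0]
  thrombocytopenia: [0.0, 0.0, 100.0, 1000.0, 2000.0]
  hypertension:     [0.0, 50.0, 150.0, 500.0, 800.0]
  fatigue:          [0.0, 30.0, 300.0, 600.0, 600.0]
  hfs:              [0.0, 40.0, 400.0, 800.0, 800.0]
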