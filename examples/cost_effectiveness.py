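"""Cost-effectiveness of biomarker-guided sunitinib dosing.

Runs fixed dosing and sVEGFR-3-guided dosing (escalate while the decrease
from individual baseline is below 25%) on one 120-patient GIST population
over 5 years, prices every capsule, visit and AE event, converts daily
utilities into QALYs, and prints the incremental cost-effectiveness ratio.
"""

import tkisim as tk

N, SEED = 120, 29
HORIZON_W = 5 * 365.25 / 7
params = tk.default_parameter_set(tk.SUNITINIB)
pop = tk.sample_population(N, tk.SUNITINIB, SEED, params)

frames = {}
for name, adapt, thr in (("fixed", "none", None),
                         ("sVEGFR-3-guided", "BAD_sVEGFR3", 0.25)):
    proto = tk.Protocol(drug=tk.SUNITINIB, schedule="CD", start_dose=37.5,
                        dose_pool=tk.SUNITINIB_POOL, adaptation=adapt,
                        threshold=thr, horizon_weeks=HORIZON_W,
                        os_model="BAD")
    res = tk.run_trial(pop, proto, params, seed=SEED)
    df = tk.evaluate_economics(res)
    frames[name] = df
    print(f"{name:16s}: median {df['lyg'].median():.2f} life-years, "
          f"{df['qaly'].median():.2f} QALYs, "
          f"EUR {df['cost_total'].median():,.0f} total cost")

icer = tk.compute_icer(frames["sVEGFR-3-guided"], frames["fixed"],
                       n_boot=300, seed=SEED)
for eff, label in (("per_lyg", "life-year"), ("per_qaly", "QALY")):
    v = icer[f"icer_{eff}"]
    if isinstance(v, float):
        lo, hi = icer[f"icer_{eff}_ci"]
        print(f"ICER per {label}: EUR {v:,.0f} (95% CI {lo:,.0f} to {hi:,.0f})")
    else:
        print(f"ICER per {label}: {v}")
print("ICER = incremental cost / incremental effect vs fixed dosing; "
      "common thresholds for acceptability are EUR 57,000-80,000 per QALY.")
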