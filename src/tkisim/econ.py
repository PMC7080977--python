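"""Cost-effectiveness analysis of sunitinib dosing strategies.

Per patient, over a 5-year horizon: life-years (LYG), daily utility values
(multiplicative across the five modeled adverse events and disease status),
quality-adjusted life-years

``QALY_i = LYG_i * sum_j UV_ij / t_treatment``

(mean daily utility during treatment times life-years), and itemized costs
(drug by minimal-capsule decomposition, follow-up tariffs on the monitoring
calendar, per-event AE management costs). Strategy comparisons report
incremental cost-effectiveness ratios (ICERs) on arm medians with bootstrap
percentile confidence intervals, the reference arm being fixed dosing under
common random numbers.

Costs and utilities are pure configuration; bundled defaults are
placeholder tariffs. No discounting by default (a yearly rate is available
for sensitivity analyses).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trial import AE_NAMES, TrialResult, lab_days

HOURS_PER_YEAR = 24 * 365.25


@dataclass
class CostConfig:
    capsule_prices: dict[float, float]        # strength mg -> EUR
    followup: dict[str, float]                # visit / lab_panel / radiology
    ae_event_costs: dict[str, list[float]]    # per AE, grade 0..4

    def validate(self) -> None:
        bad = [f"capsule {s}" for s, p in self.capsule_prices.items() if p < 0]
        bad += [f"followup {k}" for k, v in self.followup.items() if v < 0]
        bad += [f"ae {a}[{g}]" for a, row in self.ae_event_costs.items()
                for g, v in enumerate(row) if v < 0]
        if bad:
            raise ValueError("negative prices: " + ", ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostConfig":
        raw = yaml.safe_load(open(path))
        cfg = cls(capsule_prices={float(k): float(v)
                                  for k, v in raw["capsule_prices"].items()},
                  followup={k: float(v) for k, v in raw["followup"].items()},
                  ae_event_costs={k: [float(x) for x in v]
                                  for k, v in raw["ae_event_costs"].items()})
        cfg.validate()
        return cfg


@dataclass
class UtilityTable:
    baseline: float
    disease_status: dict[str, float]          # stable / progressed
    ae_factors: dict[str, list[float]]        # per AE, grade 0..4

    def validate(self) -> None:
        bad = []
        if not 0 <= self.baseline <= 1:
            bad.append("baseline")
        for k, v in self.disease_status.items():
            if not 0 <= v <= 1:
                bad.append(f"disease {k}")
        for a, row in self.ae_factors.items():
            if row[0] != 1.0:
                bad.append(f"{a} grade-0 factor must be 1")
            for g, v in enumerate(row):
                if not 0 <= v <= 1:
                    bad.append(f"{a}[{g}]")
        if bad:
            raise ValueError("utility values outside [0,1]: " + ", ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UtilityTable":
        raw = yaml.safe_load(open(path))
        tab = cls(baseline=float(raw["baseline"]),
                  disease_status={k: float(v)
                                  for k, v in raw["disease_status"].items()},
                  ae_factors={k: [float(x) for x in v]
                              for k, v in raw["ae_factors"].items()})
        tab.validate()
        return tab


def default_cost_config() -> CostConfig:
    res = importlib.resources.files("tkisim.data") / "costs_sunitinib.yaml"
    with importlib.resources.as_file(res) as p:
        return CostConfig.from_yaml(p)


def default_utility_table() -> UtilityTable:
    res = importlib.resources.files("tkisim.data") / "utilities.yaml"
    with importlib.resources.as_file(res) as p:
        return UtilityTable.from_yaml(p)


# ---------------------------------------------------------------------------
# capsule decomposition
# ---------------------------------------------------------------------------

def decompose_dose(dose: float, prices: dict[float, float]
                   ) -> tuple[dict[float, int], float]:
    """Minimal-capsule decomposition of a daily dose; ties by lowest price.

    Exhaustive dynamic program on tenths of mg. Raises if the dose cannot
    be composed from the available strengths.
    """
    if dose == 0:
        return {}, 0.0
    target = int(round(dose * 10))
    strengths = sorted(prices, reverse=True)
    units = {s: int(round(s * 10)) for s in strengths}
    # dp[v] = (capsule count, cost, composition)
    dp: list[tuple[int, float, dict] | None] = [None] * (target + 1)
    dp[0] = (0, 0.0, {})
    for v in range(1, target + 1):
        best = None
        for s in strengths:
            u = units[s]
            if u <= v and dp[v - u] is not None:
                cnt, cost, comp = dp[v - u]
                cand = (cnt + 1, cost + prices[s])
                if best is None or cand < (best[0], best[1]):
                    comp2 = dict(comp)
                    comp2[s] = comp2.get(s, 0) + 1
                    best = (cand[0], cand[1], comp2)
        dp[v] = best
    if dp[target] is None:
        raise ValueError(f"dose {dose} mg not decomposable into strengths "
                         f"{sorted(prices)}")
    cnt, cost, comp = dp[target]
    return comp, cost


# ---------------------------------------------------------------------------
# per-patient outcomes
# ---------------------------------------------------------------------------

@dataclass
class EconOutcome:
    patient_id: int
    lyg: float                 # life-years within horizon
    t_treatment_days: float
    qaly: float
    cost_drug: float
    cost_followup: float
    cost_ae: float

    @property
    def cost_total(self) -> float:
        return self.cost_drug + self.cost_followup + self.cost_ae


def compute_costs(result: TrialResult, i: int, config: CostConfig,
                  horizon_years: float = 5.0) -> dict[str, float]:
    """Itemized costs for patient ``i`` truncated at the horizon."""
    horizon_d = int(horizon_years * 365.25)
    last_day = min(horizon_d, result.days[-1])
    death_d = result.death_time_h[i] / 24.0
    drop_d = result.dropout_time_h[i] / 24.0
    end_trt = min(last_day, death_d, drop_d)

    decomp_cost = lru_cache(maxsize=None)(
        lambda d: decompose_dose(d, config.capsule_prices)[1])
    doses = result.dose_given[i, :last_day + 1]
    cost_drug = float(sum(decomp_cost(float(d)) for d in doses if d > 0))

    visit_cost = config.followup["visit"] + config.followup["lab_panel"]
    cost_fu = sum(visit_cost for d in lab_days(last_day) if d <= end_trt)
    cost_fu += sum(config.followup["radiology"]
                   for d in range(84, last_day + 1, 84) if d <= death_d)

    cost_ae = 0.0
    for ae in AE_NAMES:
        g = result.true_grades.get(ae)
        if g is None:
            continue
        row = config.ae_event_costs.get(ae)
        if row is None:
            continue
        gi = g[i, :last_day + 1].astype(int)
        prev = 0
        for day, grade in enumerate(gi):
            if grade < 0:
                break
            if grade > prev:
                cost_ae += row[min(grade, len(row) - 1)]
            prev = grade
    return {"drug": cost_drug, "followup": float(cost_fu), "ae": float(cost_ae)}


def compute_utility_series(result: TrialResult, i: int, table: UtilityTable,
                           horizon_years: float = 5.0) -> np.ndarray:
    """Daily UV_ij during treatment: baseline x AE factors x disease status."""
    horizon_d = int(horizon_years * 365.25)
    death_d = result.death_time_h[i] / 24.0
    drop_d = result.dropout_time_h[i] / 24.0
    end_d = min(death_d, drop_d)
    end_trt = int(min(horizon_d, result.days[-1],
                      math.floor(end_d) if math.isfinite(end_d) else horizon_d))
    prog_d = result.progression_time_h[i] / 24.0
    uv = np.full(end_trt + 1, table.baseline)
    for ae in AE_NAMES:
        g = result.true_grades.get(ae)
        if g is None or ae not in table.ae_factors:
            continue
        fac = np.asarray(table.ae_factors[ae])
        gi = np.clip(g[i, :end_trt + 1].astype(int), 0, len(fac) - 1)
        uv *= fac[gi]
    status = np.where(np.arange(end_trt + 1) >= prog_d,
                      table.disease_status["progressed"],
                      table.disease_status["stable"])
    return uv * status


def compute_qaly(uv_series: np.ndarray, lyg: float,
                 t_treatment_days: float) -> float:
    """Eq.-style QALY: LYG x (sum of daily UV) / treatment days."""
    if t_treatment_days <= 0:
        raise ValueError("treatment duration must be > 0")
    return float(lyg * np.sum(uv_series) / t_treatment_days)


def evaluate_economics(result: TrialResult, config: CostConfig | None = None,
                       table: UtilityTable | None = None,
                       horizon_years: float = 5.0,
                       discount_rate: float = 0.0) -> pd.DataFrame:
    """Per-patient economic outcomes for one simulated arm."""
    config = config or default_cost_config()
    table = table or default_utility_table()
    horizon_h = horizon_years * 365.25 * 24.0
    rows = []
    for i in range(result.n):
        lyg = min(result.death_time_h[i], horizon_h) / HOURS_PER_YEAR
        uv = compute_utility_series(result, i, table, horizon_years)
        t_trt = float(uv.size)
        qaly = compute_qaly(uv, lyg, t_trt)
        costs = compute_costs(result, i, config, horizon_years)
        if discount_rate > 0:
            # crude mid-horizon discounting for sensitivity analysis
            f = (1 + discount_rate) ** (-lyg / 2)
            qaly *= f
            costs = {k: v * f for k, v in costs.items()}
        rows.append({"id": int(result.patient_ids[i]), "lyg": float(lyg),
                     "t_treatment_days": t_trt, "qaly": qaly,
                     "cost_drug": costs["drug"],
                     "cost_followup": costs["followup"],
                     "cost_ae": costs["ae"],
                     "cost_total": sum(costs.values())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

def _median_icer(arm: pd.DataFrame, ref: pd.DataFrame, effect: str) -> float | str:
    dc = arm["cost_total"].median() - ref["cost_total"].median()
    de = arm[effect].median() - ref[effect].median()
    if de == 0:
        return "dominated" if dc > 0 else ("dominant" if dc < 0 else "equivalent")
    icer = dc / de
    if de < 0:
        return "dominated" if dc >= 0 else icer
    return icer


def compute_icer(arm: pd.DataFrame, ref: pd.DataFrame, n_boot: int = 1000,
                 seed: int = 0, ci: float = 95.0) -> dict:
    """ICERs (EUR per life-year and per QALY) on arm medians, with
    bootstrap-over-patients percentile intervals. Non-positive effect
    differences are reported as dominance classifications."""
    out = {}
    rng = np.random.default_rng(seed)
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    for effect, label in (("lyg", "per_lyg"), ("qaly", "per_qaly")):
        point = _median_icer(arm, ref, effect)
        out[f"icer_{label}"] = point
        boots = []
        n_a, n_r = len(arm), len(ref)
        for _ in range(n_boot):
            a = arm.iloc[rng.integers(0, n_a, n_a)]
            r = ref.iloc[rng.integers(0, n_r, n_r)]
            v = _median_icer(a, r, effect)
            if isinstance(v, float):
                boots.append(v)
        if boots:
            out[f"icer_{label}_ci"] = (float(np.percentile(boots, lo)),
                                       float(np.percentile(boots, hi)))
        else:
            out[f"icer_{label}_ci"] = (math.nan, math.nan)
    return out


def cea_table(arms: dict[str, pd.DataFrame], reference: str,
              results: dict[str, TrialResult] | None = None,
              n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Summary table: median life-years, QALYs, costs and ICERs per arm."""
    rows = []
    ref = arms[reference]
    for name, df in arms.items():
        row = {"arm": name,
               "lyg_median": df["lyg"].median(),
               "qaly_median": df["qaly"].median(),
               "cost_median": df["cost_total"].median()}
        if results is not None and name in results:
            row["cumulative_aes"] = int(sum(
                results[name].episode_counts[ae].sum() for ae in AE_NAMES))
        if name != reference:
            row.update(compute_icer(df, ref, n_boot=n_boot, seed=seed))
        rows.append(row)
    return pd.DataFrame(rows)
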