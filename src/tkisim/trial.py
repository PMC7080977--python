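"""Virtual-trial engine.

Orchestrates the coupled framework for a whole population: dosing per
schedule (continuous daily, twice daily, once weekly, once every two
weeks), the clinical monitoring calendar, CTCAE-based withhold/resume/
reduce rules, optional biomarker-guided dose adaptation, tumor dynamics,
and overall-survival/dropout event generation.

Monitoring calendar: ANC, platelets, and dBP are evaluated only on days
15, 29, 43, 57, 85, 113, and every 12 weeks thereafter; fatigue and HFS
are spontaneously reported and evaluated daily. Dose decisions use the
*observed* grades (what the clinic has seen), while outcome summaries use
the true daily simulated grades.

Common random numbers: every stochastic draw (survival/dropout uniforms,
daily categorical-AE uniforms) comes from a stream keyed on (seed, patient
id, purpose) and is independent of the protocol, so different arms or
cutoffs can be compared on identical randomness.

The engine integrates all patients simultaneously on a shared fixed step
(default 2 h): exact matrix-exponential pharmacokinetics, exact turnover
updates for piecewise-constant drive, RK4 for the transit chains, and
trapezoidal accumulation of the event-time cumulative hazards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import expit as _expit

from . import biomarkers as bm
from .params import AXITINIB, SUNITINIB, ParameterSet
from .pk import pk_system
from .population import VirtualPatient
from .survival import SurvivalOutcome
from .tumor import ProgressionRule, bernoulli_step

# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

SUNITINIB_POOL = (0.0, 12.5, 25.0, 37.5, 50.0, 62.5, 75.0)
#: high-dose extension (100-700 mg in 100 mg steps); intermittent schedules
#: step down within the extension range, not onto the daily-dose ladder
SUNITINIB_POOL_HIGH = (0.0,) + tuple(float(d) for d in range(100, 701, 100))
AXITINIB_POOL = (0.0, 2.0, 5.0, 7.0, 10.0)
AXITINIB_POOL_QW = (0.0,) + tuple(float(d) for d in range(10, 81, 10))
AXITINIB_POOL_Q2W = (0.0,) + tuple(float(d) for d in range(80, 141, 20))

DEFAULT_LAB_DAYS = (15, 29, 43, 57, 85, 113)
SCHEDULE_INTERVAL_H = {"CD": 24.0, "BID": 12.0, "QW": 168.0, "Q2W": 336.0}

AE_NAMES = ("neutropenia", "thrombocytopenia", "hypertension", "fatigue", "hfs")
SEVERE_GRADE = {"neutropenia": 3, "thrombocytopenia": 3, "hypertension": 3,
                "fatigue": 2, "hfs": 2}
ULTRA_GRADE = {"neutropenia": 4, "thrombocytopenia": 4, "hypertension": 4,
               "fatigue": 3, "hfs": 3}
ADAPTATIONS = ("none", "TDM", "TAD_ANC", "TAD_dBP", "BAD_sVEGFR3")


def lab_days(horizon_days: int) -> list[int]:
    """Clinical lab/BP monitoring days: 15, 29, 43, 57, 85, 113, then q12w."""
    days = [d for d in DEFAULT_LAB_DAYS if d <= horizon_days]
    d = DEFAULT_LAB_DAYS[-1] + 84
    while d <= horizon_days:
        days.append(d)
        d += 84
    return days


@dataclass
class Protocol:
    drug: str
    schedule: str                 # CD | BID | QW | Q2W
    start_dose: float             # mg per administration
    dose_pool: tuple[float, ...]  # ascending, contains 0
    adaptation: str = "none"
    threshold: float | None = None   # ng/ml for TDM; fraction otherwise
    horizon_weeks: float = 102.0
    monitoring_days: tuple[int, ...] | None = None  # None -> standard calendar
    os_model: str | None = None   # sunitinib: "TAD" or "BAD"; None -> by adaptation
    allow_down_titration: bool = False
    progression_rule: ProgressionRule = field(default_factory=ProgressionRule)

    def __post_init__(self):
        pool = tuple(sorted(self.dose_pool))
        if pool != tuple(self.dose_pool):
            raise ValueError("dose pool must be sorted ascending")
        if 0.0 not in pool:
            raise ValueError("dose pool must contain 0")
        if self.start_dose not in pool:
            raise ValueError("start dose must be in the dose pool")
        if self.schedule not in SCHEDULE_INTERVAL_H:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.adaptation not in ADAPTATIONS:
            raise ValueError(f"unknown adaptation {self.adaptation!r}")
        if self.adaptation != "none" and self.threshold is None:
            raise ValueError("adaptation requires a threshold")

    @property
    def horizon_days(self) -> int:
        return int(round(self.horizon_weeks * 7))

    def resolved_os_model(self) -> str:
        """Sunitinib OS framework: toxicity-driven (TAD) unless the arm is
        sVEGFR-3-guided, which runs in the biomarker-driven (BAD) framework."""
        if self.drug == AXITINIB:
            return "axitinib"
        if self.os_model is not None:
            return self.os_model
        return "BAD" if self.adaptation == "BAD_sVEGFR3" else "TAD"


# ---------------------------------------------------------------------------
# dose-decision rules (pure functions; the engine applies them per patient)
# ---------------------------------------------------------------------------

def apply_toxicity_rules(grades: dict[str, int], counters: dict[str, int],
                         current_dose: float, pool: tuple[float, ...],
                         withheld: bool = False,
                         pending_reduction: bool = False
                         ) -> tuple[str, float, bool]:
    """CTCAE withhold/resume/reduce logic at one decision time.

    Returns ``(action, dose_after, pending_reduction)`` with action in
    {continue, withhold, resume_same, resume_reduced}. A first severe
    toxicity (>= G3 labs, >= G2 fatigue/HFS) withholds until recovery
    (<= G1 in all monitored AEs) and resumes at the same dose; a repeated
    (occurrence count > 1) or very severe (G4 labs, G3 fatigue/HFS) event
    resumes one dose level lower (floor at 0).
    """
    severe_now = [ae for ae, g in grades.items() if g >= SEVERE_GRADE[ae]]
    if severe_now:
        reduce = pending_reduction or any(
            grades[ae] >= ULTRA_GRADE[ae] or counters.get(ae, 0) > 1
            for ae in severe_now)
        return "withhold", current_dose, reduce
    if withheld:
        if all(g <= 1 for g in grades.values()):
            if pending_reduction:
                i = pool.index(current_dose)
                return "resume_reduced", pool[max(0, i - 1)], False
            return "resume_same", current_dose, False
        return "withhold", current_dose, pending_reduction
    return "continue", current_dose, pending_reduction


def apply_biomarker_rule(signal: float, adaptation: str, threshold: float,
                         current_dose: float, pool: tuple[float, ...],
                         withheld: bool = False,
                         allow_down: bool = False) -> float:
    """Biomarker-guided dose adjustment at a lab decision time.

    ``signal`` convention: TDM — total trough concentration (ng/ml);
    TAD_ANC — fractional ANC decrease from the population baseline;
    TAD_dBP — fractional dBP increase from individual baseline;
    BAD_sVEGFR3 — fractional sVEGFR-3 decrease from individual baseline.
    A sub-target signal (below the cutoff) steps the dose one level up,
    capped at the pool maximum; at-or-beyond-target holds (or steps down
    one level when down-titration is enabled). Toxicity rules take
    precedence: no adjustment while withheld.
    """
    if withheld or adaptation == "none":
        return current_dose
    sub_target = signal < threshold
    i = pool.index(current_dose)
    if sub_target:
        return pool[min(len(pool) - 1, i + 1)]
    if allow_down:
        return pool[max(0, i - 1)]
    return current_dose


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Population-level longitudinal output of one simulated arm."""

    protocol: Protocol
    patient_ids: np.ndarray
    days: np.ndarray                       # d (daily grid, day 0 .. horizon)
    dose_given: np.ndarray                 # (n, n_days) mg administered per day
    series: dict[str, np.ndarray]          # (n, n_days) biomarker values
    true_grades: dict[str, np.ndarray]     # (n, n_days) int8, -1 after death
    death_time_h: np.ndarray               # inf = alive at horizon
    dropout_time_h: np.ndarray             # inf = never
    progression_time_h: np.ndarray         # inf = never
    baseline_tumor: np.ndarray
    episode_counts: dict[str, np.ndarray]  # observed severe episodes per AE

    @property
    def n(self) -> int:
        return self.patient_ids.size

    def outcome(self, i: int) -> SurvivalOutcome:
        d = self.death_time_h[i]
        o = self.dropout_time_h[i]
        return SurvivalOutcome(
            death_time=None if np.isinf(d) else float(d),
            dropout_time=None if np.isinf(o) else float(o),
            horizon=self.protocol.horizon_days * 24.0)

    def long_frame(self, patients: list[int] | None = None) -> pd.DataFrame:
        """Long-format export: one row per (patient, day, series)."""
        ids = self.patient_ids if patients is None else np.asarray(patients)
        idx = np.searchsorted(self.patient_ids, ids)
        rows = []
        for name, arr in self.series.items():
            for j, i in enumerate(idx):
                rows.append(pd.DataFrame({
                    "id": ids[j], "time_h": self.days * 24.0,
                    "name": name, "value": arr[i]}))
        for ae, g in self.true_grades.items():
            for j, i in enumerate(idx):
                rows.append(pd.DataFrame({
                    "id": ids[j], "time_h": self.days * 24.0,
                    "name": f"grade_{ae}", "value": g[i].astype(float)}))
        return pd.concat(rows, ignore_index=True)

    def event_table(self, t_weeks: float = 102.0) -> pd.DataFrame:
        t_h = t_weeks * 7 * 24
        return pd.DataFrame({
            "id": self.patient_ids,
            "death_time_h": self.death_time_h,
            "dropout_time_h": self.dropout_time_h,
            f"alive_at_{int(t_weeks)}w": self.death_time_h > t_h,
        })


def summarize_outcomes(result: TrialResult, t_weeks: float,
                       ae_metric: str = "max_grade") -> dict:
    """Survival %, per-AE severe incidence %, cumulative AE count.

    Survival is the simulated true fraction alive at ``t_weeks`` (dropout
    does not censor). The per-AE "max %" is, by default, the fraction of
    patients whose maximum grade over the record reached the severe level
    (>= G3; >= G2 for fatigue/HFS); ``ae_metric='point_prevalence'``
    switches to the maximum-over-days prevalence of severe grade among
    patients alive that day. Cumulative AEs counts entries into severe
    grade on the true daily series over the whole record.
    """
    if result.n == 0:
        raise ValueError("no records to summarize")
    if ae_metric not in ("max_grade", "point_prevalence"):
        raise ValueError(f"unknown ae_metric {ae_metric!r}")
    t_h = t_weeks * 7 * 24.0
    out = {"survival_pct": 100.0 * float(np.mean(result.death_time_h > t_h))}
    day_h = result.days * 24.0
    alive = result.death_time_h[:, None] > day_h[None, :]
    n_alive = np.maximum(alive.sum(axis=0), 1)
    cum = 0
    for ae in AE_NAMES:
        g = result.true_grades.get(ae)
        if g is None:
            continue
        sev = (g >= SEVERE_GRADE[ae]) & alive
        if ae_metric == "max_grade":
            out[f"{ae}_max_pct"] = 100.0 * float(sev.any(axis=1).mean())
        else:
            out[f"{ae}_max_pct"] = 100.0 * float((sev.sum(axis=0) / n_alive).max())
        entries = sev[:, 1:] & ~sev[:, :-1]
        cum += int(entries.sum()) + int(sev[:, 0].sum())
    out["cumulative_ae_count"] = cum
    return out


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _per_patient_rng_u(seed_key, purpose: str) -> float:
    s, pid = seed_key
    tag = {"os": 1, "dropout": 2}[purpose]
    rng = np.random.default_rng(np.random.SeedSequence((s, pid, 1000 + tag)))
    return float(rng.uniform())


def _daily_uniforms(seed_key, purpose: str, n_days: int) -> np.ndarray:
    s, pid = seed_key
    tag = {"fatigue": 3, "hfs": 4}[purpose]
    rng = np.random.default_rng(np.random.SeedSequence((s, pid, 1000 + tag)))
    return rng.uniform(size=n_days)


def run_trial(population: list[VirtualPatient], protocol: Protocol,
              params: ParameterSet, seed: int, step_h: float = 2.0
              ) -> TrialResult:
    """Simulate one arm for a whole population; deterministic under seed."""
    if params.drug != protocol.drug:
        raise ValueError("protocol and parameter set disagree on drug")
    for p in population:
        if p.drug != protocol.drug:
            raise ValueError("population and protocol disagree on drug")
    if 24.0 % step_h or SCHEDULE_INTERVAL_H[protocol.schedule] % step_h:
        raise ValueError("step must divide both 24 h and the dosing interval")

    n = len(population)
    drug = protocol.drug
    sun = drug == SUNITINIB
    n_days = protocol.horizon_days
    horizon_h = n_days * 24.0
    steps_per_day = int(round(24.0 / step_h))
    n_steps = n_days * steps_per_day
    labs = set(lab_days(n_days)) if protocol.monitoring_days is None \
        else set(protocol.monitoring_days)
    dose_interval = SCHEDULE_INTERVAL_H[protocol.schedule]

    # --- per-patient constants ------------------------------------------
    getp = lambda name: np.array([p.individual(params, name) for p in population])

    n_cpt = 3 if sun else 2
    P = np.empty((n, n_cpt, n_cpt))
    obs_rows = np.empty((n, 1 if not sun else 2, n_cpt))
    for i, p in enumerate(population):
        A, obs = pk_system(p, params)
        P[i] = expm(A * step_h)
        obs_rows[i] = obs

    base_v3 = getp("base_svegfr3")
    kout_v3 = 1.0 / params["mrt_svegfr3_h"]
    ic50_v3 = getp("ic50_svegfr3")
    imax_v3 = params["imax_svegfr3"]
    base_dbp = getp("base_dbp")
    if sun:
        base_skit = getp("base_skit")
        kout_skit = 1.0 / params["mrt_skit_h"]
        ic50_skit = getp("ic50_skit")
        imax_skit = params["imax_skit"]
        kout_dbp = np.full(n, 1.0 / params["mrt_dbp_h"])
        slope_dbp = getp("slope_dbp")
        base_anc, slope_anc = getp("base_anc"), getp("slope_anc")
        ktr_anc = 4.0 / getp("mtt_anc_h")
        gamma_anc = params["gamma_anc"]
        base_plt, emax_plt = getp("base_plt"), getp("emax_plt")
        ktr_plt = 4.0 / np.full(n, params["mtt_plt_h"])
        gamma_plt = params["gamma_plt"]
        fat_model = bm.CategoricalAEModel.from_params(params, "fatigue")
        hfs_model = bm.CategoricalAEModel.from_params(params, "hfs")
    else:
        kout_dbp = 1.0 / getp("mrt_dbp_h")
        emax_dbp = getp("emax_dbp")
        ec50_dbp = params["ec50_dbp"]

    kg = getp("tum_kg")
    kill_scale = np.exp([p.etas.get("tum_kv3", 0.0) for p in population])
    lam_res = params["tum_lambda_res"]
    b_logis = kg / params["tum_tmax"]
    bsld = np.array([p.baseline_tumor for p in population])

    # survival model (per framework) and dropout
    os_model = protocol.resolved_os_model()
    if os_model == "TAD":
        os_scale, os_shape = params["os_tad_weib_scale_h"], params["os_tad_weib_shape"]
        bsld_term = params["os_tad_beta_bsld"] * (bsld - params["bsld_ref"])
    elif os_model == "BAD":
        os_scale, os_shape = params["os_bad_weib_scale_h"], params["os_bad_weib_shape"]
        bsld_term = params["os_bad_beta_bsld"] * (bsld - params["bsld_ref"])
    else:
        os_scale, os_shape = params["os_weib_scale_h"], params["os_weib_shape"]
        bsld_term = np.zeros(n)

    u_os = np.array([_per_patient_rng_u(p.seed_key, "os") for p in population])
    u_drop = np.array([_per_patient_rng_u(p.seed_key, "dropout") for p in population])
    target_os = -np.log(u_os)
    target_drop = -np.log(u_drop)
    U_fat = np.vstack([_daily_uniforms(p.seed_key, "fatigue", n_days + 1)
                       for p in population]) if sun else None
    U_hfs = np.vstack([_daily_uniforms(p.seed_key, "hfs", n_days + 1)
                       for p in population]) if sun else None

    # --- state -----------------------------------------------------------
    x = np.zeros((n, n_cpt))
    v3 = base_v3.copy()
    dbp = base_dbp.copy()
    if sun:
        skit = base_skit.copy()
        anc_chain = np.tile(base_anc[:, None], (1, 5))
        plt_chain = np.tile(base_plt[:, None], (1, 5))
    sld = bsld.copy()
    nadir = bsld.copy()
    prog_time = np.full(n, np.inf)
    H_os = np.zeros(n)
    H_drop = np.zeros(n)
    h_os_prev = np.zeros(n)
    h_drop_prev = np.zeros(n)
    death_t = np.full(n, np.inf)
    drop_t = np.full(n, np.inf)

    pool = tuple(protocol.dose_pool)
    level = np.full(n, pool.index(protocol.start_dose), dtype=int)
    withheld = np.zeros(n, dtype=bool)
    pending_red = np.zeros(n, dtype=bool)
    counters = {ae: np.zeros(n, dtype=int) for ae in AE_NAMES}
    in_episode = {ae: np.zeros(n, dtype=bool) for ae in AE_NAMES}
    obs_grade = {ae: np.zeros(n, dtype=int) for ae in AE_NAMES}
    fat_grade = np.zeros(n, dtype=int)
    hfs_grade = np.zeros(n, dtype=int)

    # rolling 24 h AUC of the TDM (total) concentration
    ring = np.zeros((n, steps_per_day))
    auc24 = np.zeros(n)
    ring_i = 0

    def conc_arrays():
        c = np.einsum("nij,nj->ni", obs_rows, x)
        total = c.sum(axis=1)
        return c, total

    # --- storage ---------------------------------------------------------
    days = np.arange(n_days + 1)
    store_names = ["conc_total", "auc24", "svegfr3", "dbp", "sld"] + \
        (["skit", "anc", "platelets"] if sun else [])
    series = {k: np.zeros((n, n_days + 1), dtype=np.float32) for k in store_names}
    tracked_aes = AE_NAMES if sun else ("hypertension",)
    true_grades = {ae: np.full((n, n_days + 1), -1, dtype=np.int8)
                   for ae in tracked_aes}
    dose_given = np.zeros((n, n_days + 1), dtype=np.float32)

    ae_lab = ("neutropenia", "thrombocytopenia", "hypertension") if sun \
        else ("hypertension",)
    ae_daily = ("fatigue", "hfs") if sun else ()
    monitored = ae_lab + ae_daily

    def record_day(d):
        _, total = conc_arrays()
        series["conc_total"][:, d] = total
        series["auc24"][:, d] = auc24
        series["svegfr3"][:, d] = v3
        series["dbp"][:, d] = dbp
        series["sld"][:, d] = sld
        if sun:
            series["skit"][:, d] = skit
            series["anc"][:, d] = anc_chain[:, 4]
            series["platelets"][:, d] = plt_chain[:, 4]
        alive = np.isinf(death_t)
        for ae in tracked_aes:
            if ae == "neutropenia":
                vals = bm.grade_array(np.maximum(anc_chain[:, 4], 1e-6), ae)
            elif ae == "thrombocytopenia":
                vals = bm.grade_array(np.maximum(plt_chain[:, 4], 1e-6), ae)
            elif ae == "hypertension":
                vals = bm.grade_array(dbp, ae)
            elif ae == "fatigue":
                vals = fat_grade
            else:
                vals = hfs_grade
            true_grades[ae][alive, d] = vals.astype(np.int8)[alive]

    def decide(d):
        """Daily decision block at day d (pre-dose)."""
        nonlocal fat_grade, hfs_grade
        active = np.isinf(death_t) & np.isinf(drop_t)
        if sun:
            # categorical AEs evaluated daily (spontaneously reported)
            rel_dec = np.maximum(0.0, (base_v3 - v3) / base_v3)
            for model, U, g in ((fat_model, U_fat, fat_grade),
                                (hfs_model, U_hfs, hfs_grade)):
                lp = model.beta * rel_dec + model.kappa * g
                cum = _expit(model.intercepts[None, :] + lp[:, None])
                g[:] = (U[:, d][:, None] < cum).sum(axis=1)
            obs_grade["fatigue"][:] = fat_grade
            obs_grade["hfs"][:] = hfs_grade
        # withheld patients are re-checked weekly outside the routine
        # calendar (recovery monitoring during a toxicity hold)
        recheck = withheld & active if (d % 7 == 0) else np.zeros(n, bool)
        is_lab = d in labs
        if recheck.any() and not is_lab:
            for ae in ae_lab:
                if ae == "neutropenia":
                    g = bm.grade_array(np.maximum(anc_chain[:, 4], 1e-6), ae)
                elif ae == "thrombocytopenia":
                    g = bm.grade_array(np.maximum(plt_chain[:, 4], 1e-6), ae)
                else:
                    g = bm.grade_array(dbp, ae)
                obs_grade[ae][recheck] = g[recheck]
        if is_lab:
            for ae in ae_lab:
                if ae == "neutropenia":
                    g = bm.grade_array(np.maximum(anc_chain[:, 4], 1e-6), ae)
                elif ae == "thrombocytopenia":
                    g = bm.grade_array(np.maximum(plt_chain[:, 4], 1e-6), ae)
                else:
                    g = bm.grade_array(dbp, ae)
                obs_grade[ae][:] = g
        # episode accounting on observed grades (categorical daily; labs when
        # observed at lab days or withheld-patient rechecks)
        for ae in (monitored if (is_lab or recheck.any()) else ae_daily):
            sev = obs_grade[ae] >= SEVERE_GRADE[ae]
            new_ep = sev & ~in_episode[ae] & active
            counters[ae][new_ep] += 1
            in_episode[ae][new_ep] = True
            ended = (obs_grade[ae] <= 1) & in_episode[ae]
            in_episode[ae][ended] = False
        # toxicity rules per flagged patient
        flagged = np.zeros(n, dtype=bool)
        for ae in (ae_daily if not is_lab else monitored):
            flagged |= obs_grade[ae] >= SEVERE_GRADE[ae]
        flagged |= withheld
        flagged &= active
        for i in np.flatnonzero(flagged):
            grades_i = {ae: int(obs_grade[ae][i]) for ae in monitored}
            counters_i = {ae: int(counters[ae][i]) for ae in monitored}
            action, dose_after, pend = apply_toxicity_rules(
                grades_i, counters_i, pool[level[i]], pool,
                withheld=bool(withheld[i]), pending_reduction=bool(pending_red[i]))
            pending_red[i] = pend
            if action == "withhold":
                withheld[i] = True
            elif action in ("resume_same", "resume_reduced"):
                withheld[i] = False
                level[i] = pool.index(dose_after)
        # biomarker adaptation at lab days only, toxicity takes precedence
        if is_lab and protocol.adaptation != "none":
            _, total = conc_arrays()
            for i in np.flatnonzero(active & ~withheld):
                if protocol.adaptation == "TDM":
                    signal = float(total[i])
                elif protocol.adaptation == "TAD_ANC":
                    signal = float((bm.ANC_POPULATION_BASELINE - anc_chain[i, 4])
                                   / bm.ANC_POPULATION_BASELINE)
                elif protocol.adaptation == "TAD_dBP":
                    signal = float((dbp[i] - base_dbp[i]) / base_dbp[i])
                else:  # BAD_sVEGFR3
                    signal = float((base_v3[i] - v3[i]) / base_v3[i])
                new_dose = apply_biomarker_rule(
                    signal, protocol.adaptation, protocol.threshold,
                    pool[level[i]], pool, withheld=False,
                    allow_down=protocol.allow_down_titration)
                level[i] = pool.index(new_dose)

    # hazard evaluation
    def hazards(t):
        tt = max(t, 1e-9)
        h0_os = (os_shape / os_scale) * (tt / os_scale) ** (os_shape - 1.0)
        prog = (prog_time <= t)
        if os_model == "TAD":
            lp = (params["os_tad_beta_dbp"] * (dbp - base_dbp) / base_dbp
                  + params["os_tad_beta_anc"] * bm.scaled_anc(anc_chain[:, 4])
                  + bsld_term)
        elif os_model == "BAD":
            lp = params["os_bad_beta_v3"] * (v3 - base_v3) / base_v3 + bsld_term
        else:
            lp = (params["os_beta_sld"] * sld / 100.0
                  + params["os_beta_prog"] * prog)
        h_os = h0_os * np.exp(lp)
        lp_d = (params["drop_beta_prog"] * prog
                + params["drop_beta_sld"] * sld / 100.0)
        if not sun:
            lp_d = lp_d + params["drop_beta_auc"] * auc24 / 1000.0
        h_drop = params["drop_lambda_h"] * np.exp(lp_d)
        return h_os, h_drop

    # --- main loop --------------------------------------------------------
    h_os_prev, h_drop_prev = hazards(0.0)
    record_day(0)
    decide(0)

    for k in range(n_steps):
        t0 = k * step_h
        t1 = t0 + step_h
        # dose administration at t0 (post-decision)
        if t0 % dose_interval == 0:
            can_dose = (np.isinf(death_t) & np.isinf(drop_t) & ~withheld
                        & (np.array([pool[l] for l in level]) > 0))
            amt = np.array([pool[l] for l in level])
            x[can_dose, 0] += amt[can_dose]
            day_idx = int(t0 // 24)
            dose_given[can_dose, day_idx] += amt[can_dose]

        # drives at step start
        _, total0 = conc_arrays()
        rel_dec_v3 = np.maximum(0.0, (base_v3 - v3) / base_v3)

        # PK propagation
        x = np.einsum("nij,nj->ni", P, x)
        _, total1 = conc_arrays()

        # rolling daily AUC (trapezoid increment over the step)
        inc = 0.5 * (total0 + total1) * step_h
        auc24 += inc - ring[:, ring_i]
        ring[:, ring_i] = inc
        ring_i = (ring_i + 1) % steps_per_day

        # biomarker updates (drive at step start; exact turnover updates)
        eff_v3 = imax_v3 * total0 / (ic50_v3 + total0)
        v3 = bm.indirect_step(v3, kout_v3 * base_v3 * (1 - eff_v3), kout_v3, step_h)
        if sun:
            eff_sk = imax_skit * total0 / (ic50_skit + total0)
            skit = bm.indirect_step(
                skit, kout_skit * base_skit * (1 - eff_sk), kout_skit, step_h)
            stim = slope_dbp * auc24
        else:
            stim = emax_dbp * total0 / (ec50_dbp + total0)
        dbp = bm.indirect_step(dbp, kout_dbp * base_dbp * (1 + stim), kout_dbp, step_h)
        if sun:
            e_anc = np.minimum(1.0, slope_anc * rel_dec_v3)
            anc_chain = _transit_step_vec(anc_chain, ktr_anc, base_anc,
                                          gamma_anc, e_anc, step_h)
            e_plt = np.minimum(1.0, emax_plt * auc24 / (params["auc50_plt"] + auc24))
            plt_chain = _transit_step_vec(plt_chain, ktr_plt, base_plt,
                                          gamma_plt, e_plt, step_h)

        # tumor (exact Bernoulli step, piecewise-constant kill drive)
        E = kill_scale * params["tum_kv3"] * rel_dec_v3
        if sun:
            rel_dec_sk = np.maximum(0.0, (base_skit - skit) / base_skit)
            E = E + kill_scale * (
                params["tum_kskit"] * rel_dec_sk
                + params["tum_kauc_max"] * auc24 / (params["tum_auc50"] + auc24))
        res_fac = math.exp(-lam_res * 0.5 * (t0 + t1)) if lam_res > 0 else 1.0
        sld = bernoulli_step(sld, kg - E * res_fac, b_logis, step_h)
        nadir = np.minimum(nadir, sld)
        newly_prog = np.isinf(prog_time) & (
            (sld >= (1 + protocol.progression_rule.rel_increase) * nadir)
            & (sld - nadir >= protocol.progression_rule.abs_increase))
        prog_time[newly_prog] = t1

        # hazards and event detection (trapezoid accumulation)
        h_os_new, h_drop_new = hazards(t1)
        dH_os = 0.5 * (h_os_prev + h_os_new) * step_h
        dH_dr = 0.5 * (h_drop_prev + h_drop_new) * step_h
        alive = np.isinf(death_t)
        newly_dead = alive & (H_os + dH_os >= target_os)
        if newly_dead.any():
            f = np.clip((target_os[newly_dead] - H_os[newly_dead])
                        / np.maximum(dH_os[newly_dead], 1e-300), 0, 1)
            death_t[newly_dead] = t0 + f * step_h
        on_trt = np.isinf(drop_t) & alive
        newly_drop = on_trt & (H_drop + dH_dr >= target_drop) & ~newly_dead
        if newly_drop.any():
            f = np.clip((target_drop[newly_drop] - H_drop[newly_drop])
                        / np.maximum(dH_dr[newly_drop], 1e-300), 0, 1)
            drop_t[newly_drop] = t0 + f * step_h
        H_os += dH_os
        H_drop += dH_dr
        h_os_prev, h_drop_prev = h_os_new, h_drop_new

        # day boundary: record and decide
        if t1 % 24.0 == 0:
            d = int(t1 // 24)
            record_day(d)
            if d < n_days:
                decide(d)

    drop_t = np.minimum(drop_t, death_t)
    return TrialResult(
        protocol=protocol,
        patient_ids=np.array([p.id for p in population]),
        days=days, dose_given=dose_given, series=series,
        true_grades=true_grades, death_time_h=death_t,
        dropout_time_h=drop_t, progression_time_h=prog_time,
        baseline_tumor=bsld,
        episode_counts={ae: counters[ae].copy() for ae in AE_NAMES})


def _transit_step_vec(state, ktr, base, gamma, effect, dt):
    """Vectorized RK4 step of the transit chain; state (n, 5)."""
    def rhs(s):
        circ = np.maximum(s[:, 4], 1e-9)
        fb = (base / circ) ** gamma
        prol = s[:, 0]
        d = np.empty_like(s)
        d[:, 0] = ktr * prol * (1 - effect) * fb - ktr * prol
        d[:, 1] = ktr * (prol - s[:, 1])
        d[:, 2] = ktr * (s[:, 1] - s[:, 2])
        d[:, 3] = ktr * (s[:, 2] - s[:, 3])
        d[:, 4] = ktr * (s[:, 3] - s[:, 4])
        return d
    k1 = rhs(state)
    k2 = rhs(state + 0.5 * dt * k1)
    k3 = rhs(state + 0.5 * dt * k2)
    k4 = rhs(state + dt * k3)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


# ---------------------------------------------------------------------------
# threshold scanning
# ---------------------------------------------------------------------------

#: cutoff grids for the biomarker-threshold scan
CUTOFF_GRIDS = {
    "TDM": tuple(np.arange(0.0, 80.1, 10.0)),            # ng/ml
    "TAD_ANC": tuple(np.arange(0.0, 0.801, 0.10)),       # fractional decrease
    "BAD_sVEGFR3": (0.0,) + tuple(np.arange(0.05, 0.801, 0.05)),
    "TAD_dBP": (0.0,) + tuple(np.arange(0.025, 0.401, 0.025)),
}


def scan_thresholds(population: list[VirtualPatient], protocol: Protocol,
                    params: ParameterSet, cutoffs, seed: int,
                    t_weeks: float = 102.0, step_h: float = 2.0) -> pd.DataFrame:
    """One arm per cutoff under common random numbers; IPRED decisions.

    Returns a table of cutoff vs. overall survival at ``t_weeks`` and the
    per-AE maximum severe-grade prevalence.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff grid")
    rows = []
    for c in cutoffs:
        proto = replace(protocol, threshold=float(c))
        res = run_trial(population, proto, params, seed, step_h=step_h)
        summ = summarize_outcomes(res, t_weeks)
        summ["cutoff"] = float(c)
        rows.append(summ)
    df = pd.DataFrame(rows)
    return df[["cutoff"] + [c for c in df.columns if c != "cutoff"]]
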