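"""Biomarker and adverse-event dynamics.

Five longitudinal models feed the trial engine and the survival hazards:

* **sVEGFR-3** and **sKIT** — turnover (indirect-response) models with Imax
  inhibition of the production rate by drug concentration;
* **diastolic blood pressure (dBP)** — turnover model with stimulation of
  production, linear in daily AUC for sunitinib and Emax in concentration
  for axitinib;
* **ANC** and **platelets** — transit-compartment myelosuppression
  (proliferating pool, three transit compartments, circulating pool with
  feedback ``(baseline/circ)^gamma``); ANC is driven by the relative
  sVEGFR-3 decrease, platelets by daily drug AUC;
* **fatigue** and **hand-foot syndrome** — ordered-categorical
  (proportional-odds) daily grade models with Markov dependence on the
  previous grade, driven by the relative sVEGFR-3 decrease.

Laboratory/vital AEs are graded per CTCAE v3.0 lookup tables; a value that
falls exactly on a cut point maps to the more severe grade.

The turnover updates are exact for piecewise-constant drug input (the value
the oracle tests exploit); the nonlinear transit chain is integrated with a
classical RK4 step on the simulation grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .params import AXITINIB, SUNITINIB, ParameterSet
from .pk import ConcentrationProfile, ExposureMetrics
from .population import VirtualPatient

ANC_POPULATION_BASELINE = 5.0  # 1e9 cells/L


@dataclass
class BiomarkerSeries:
    name: str                 # svegfr3 | skit | anc | platelets | dbp
    times: np.ndarray         # h
    values: np.ndarray
    baseline: float


@dataclass
class AEGradeSeries:
    ae: str                   # fatigue | hfs | neutropenia | ...
    times: np.ndarray         # h
    grades: np.ndarray        # int 0..4 (0..3 for categorical AEs)


# ---------------------------------------------------------------------------
# turnover (indirect-response) models
# ---------------------------------------------------------------------------

def indirect_step(x, kin_eff, kout, dt):
    """Exact update of dx/dt = kin_eff - kout*x over dt (kin_eff constant)."""
    xss = kin_eff / kout
    return xss + (x - xss) * np.exp(-kout * dt)


def _drive_on_grid(driver, attr="total") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(driver, ConcentrationProfile):
        return driver.times, getattr(driver, attr)
    if isinstance(driver, ExposureMetrics):
        return driver.auc_windows, driver.auc_daily
    times, values = driver
    return np.asarray(times, float), np.asarray(values, float)


def inhibition_effect(conc, imax, ic50):
    return imax * conc / (ic50 + conc)


def simulate_indirect_response(driver, params: ParameterSet,
                               patient: VirtualPatient, name: str
                               ) -> BiomarkerSeries:
    """Simulate sVEGFR-3, sKIT, or dBP for one patient.

    ``driver`` is a :class:`ConcentrationProfile` (sVEGFR-3/sKIT, axitinib
    dBP), an :class:`ExposureMetrics` or ``(times, daily_auc)`` pair
    (sunitinib dBP). The drive is held piecewise-constant between grid
    points (value at the left edge), making the update exact per interval.
    """
    if name in ("svegfr3", "skit"):
        key = "svegfr3" if name == "svegfr3" else "skit"
        base = patient.individual(params, f"base_{key}")
        kout = 1.0 / params[f"mrt_{key}_h"]
        imax = params[f"imax_{key}"]
        ic50 = patient.individual(params, f"ic50_{key}")
        t, c = _drive_on_grid(driver)
        effect = inhibition_effect(c, imax, ic50)
        kin_eff = kout * base * (1.0 - effect)
    elif name == "dbp":
        base = patient.individual(params, "base_dbp")
        if params.drug == AXITINIB:
            kout = 1.0 / patient.individual(params, "mrt_dbp_h")
            t, c = _drive_on_grid(driver)
            emax = patient.individual(params, "emax_dbp")
            stim = emax * c / (params["ec50_dbp"] + c)
        else:
            kout = 1.0 / params["mrt_dbp_h"]
            t, auc = _drive_on_grid(driver)
            slope = patient.individual(params, "slope_dbp")
            stim = slope * auc
        kin_eff = kout * base * (1.0 + stim)
    else:
        raise ValueError(f"unknown indirect-response biomarker {name!r}")
    if kout <= 0 or base <= 0:
        raise ValueError("non-positive turnover parameters")

    x = np.empty_like(t, dtype=float)
    x[0] = base
    for i in range(1, t.size):
        x[i] = indirect_step(x[i - 1], kin_eff[i - 1], kout, t[i] - t[i - 1])
    return BiomarkerSeries(name=name, times=t, values=x, baseline=base)


# ---------------------------------------------------------------------------
# transit-compartment myelosuppression
# ---------------------------------------------------------------------------

def transit_rhs(state, ktr, base, gamma, effect):
    """Friberg-type chain: prolif, 3 transit, circulating (last)."""
    prol, t1, t2, t3, circ = state
    circ_s = np.maximum(circ, 1e-9)
    feedback = (base / circ_s) ** gamma
    dprol = ktr * prol * (1.0 - effect) * feedback - ktr * prol
    return np.array([dprol,
                     ktr * (prol - t1),
                     ktr * (t1 - t2),
                     ktr * (t2 - t3),
                     ktr * (t3 - circ)])


def transit_step(state, ktr, base, gamma, effect, dt):
    """Classical RK4 step of the transit chain (effect constant over dt)."""
    k1 = transit_rhs(state, ktr, base, gamma, effect)
    k2 = transit_rhs(state + 0.5 * dt * k1, ktr, base, gamma, effect)
    k3 = transit_rhs(state + 0.5 * dt * k2, ktr, base, gamma, effect)
    k4 = transit_rhs(state + dt * k3, ktr, base, gamma, effect)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def myelosuppression_drive(driver, params: ParameterSet,
                           patient: VirtualPatient, cell: str
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(times, proliferation-inhibition effect) for the ANC or platelet chain.

    ANC: effect = slope * positive part of the relative sVEGFR-3 decrease.
    Platelets: saturating (Emax) effect of daily AUC,
    ``emax * AUC / (AUC50 + AUC)``. Effects are capped at 1 (full
    proliferation shut-off).
    """
    if cell == "anc":
        series: BiomarkerSeries = driver
        rel_dec = np.maximum(0.0, -(series.values - series.baseline) / series.baseline)
        slope = patient.individual(params, "slope_anc")
        return series.times, np.minimum(1.0, slope * rel_dec)
    if cell == "platelets":
        t, auc = _drive_on_grid(driver)
        emax = patient.individual(params, "emax_plt")
        return t, np.minimum(1.0, emax * auc / (params["auc50_plt"] + auc))
    raise ValueError(f"unknown cell line {cell!r}")


def simulate_myelosuppression(driver, params: ParameterSet,
                              patient: VirtualPatient, cell: str
                              ) -> BiomarkerSeries:
    key = "anc" if cell == "anc" else "plt"
    mtt = patient.individual(params, f"mtt_{key}_h")
    if mtt <= 0:
        raise ValueError("non-positive transit time")
    ktr = 4.0 / mtt
    base = patient.individual(params, f"base_{key}")
    gamma = params[f"gamma_{key}"]
    t, effect = myelosuppression_drive(driver, params, patient, cell)
    state = np.full(5, base)
    circ = np.empty_like(t, dtype=float)
    circ[0] = base
    for i in range(1, t.size):
        state = transit_step(state, ktr, base, gamma, effect[i - 1], t[i] - t[i - 1])
        circ[i] = state[-1]
    return BiomarkerSeries(name=cell, times=t, values=circ, baseline=base)


def transit_steady_state(base: float, gamma: float, effect: float) -> float:
    """Closed-form long-run circulating count under constant effect.

    At steady state the proliferation balance gives
    ``(1 - effect) * (base/circ)^gamma = 1``.
    """
    if effect >= 1.0:
        return 0.0
    return base * (1.0 - effect) ** (1.0 / gamma)


# ---------------------------------------------------------------------------
# ordered-categorical AEs (proportional-odds Markov)
# ---------------------------------------------------------------------------

class CategoricalAEModel:
    """Daily proportional-odds grade model (grades 0..3) with Markov state.

    ``logit P(G_t >= k | G_{t-1}, x) = theta_k + beta*x + kappa*G_{t-1}``
    with strictly decreasing intercepts ``theta_k``, so the cumulative
    probabilities are non-increasing in k by construction.
    """

    n_grades = 4  # grades 0..3

    def __init__(self, intercepts, beta: float, kappa: float):
        self.intercepts = np.asarray(intercepts, dtype=float)
        if np.any(np.diff(self.intercepts) >= 0):
            raise ValueError("intercepts must be strictly decreasing")
        self.beta = beta
        self.kappa = kappa

    @classmethod
    def from_params(cls, params: ParameterSet, ae: str) -> "CategoricalAEModel":
        pre = {"fatigue": "fat", "hfs": "hfs"}[ae]
        return cls([params[f"{pre}_int_g{k}"] for k in (1, 2, 3)],
                   params[f"{pre}_beta_v3"], params[f"{pre}_kappa"])

    def cumulative_probs(self, x: float, prev_grade: int) -> np.ndarray:
        """P(G >= k) for k = 1..3 given driver x and previous grade."""
        return expit(self.intercepts + self.beta * x + self.kappa * prev_grade)

    def grade_probs(self, x: float, prev_grade: int) -> np.ndarray:
        cum = expit(self.intercepts + self.beta * x + self.kappa * prev_grade)
        probs = np.empty(4)
        probs[0] = 1.0 - cum[0]
        probs[1:3] = cum[:2] - cum[1:]
        probs[3] = cum[2]
        if abs(probs.sum() - 1.0) > 1e-9:
            raise RuntimeError("grade probabilities do not sum to 1")
        return probs

    def transition_matrix(self, x: float) -> np.ndarray:
        return np.vstack([self.grade_probs(x, g) for g in range(self.n_grades)])

    def stationary_distribution(self, x: float) -> np.ndarray:
        """Long-run grade distribution at fixed driver, by eigen-decomposition."""
        P = self.transition_matrix(x)
        w, v = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def sample_path(self, x: np.ndarray, rng: np.random.Generator,
                    initial_grade: int = 0) -> np.ndarray:
        grades = np.empty(len(x), dtype=int)
        g = initial_grade
        for i, xi in enumerate(x):
            probs = self.grade_probs(float(xi), g)
            g = int(rng.choice(self.n_grades, p=probs))
            grades[i] = g
        return grades


def simulate_categorical_ae(driver: BiomarkerSeries, params: ParameterSet,
                            patient: VirtualPatient, ae: str, seed: int
                            ) -> AEGradeSeries:
    """Sample a daily fatigue/HFS grade path driven by sVEGFR-3 decrease."""
    if ae not in ("fatigue", "hfs"):
        raise ValueError(f"unknown categorical AE {ae!r}")
    model = CategoricalAEModel.from_params(params, ae)
    days = np.arange(0.0, driver.times[-1] + 1e-9, 24.0)
    rel_dec = np.maximum(
        0.0, -(np.interp(days, driver.times, driver.values) - driver.baseline)
        / driver.baseline)
    tag = {"fatigue": 3, "hfs": 4}[ae]
    rng = np.random.default_rng(np.random.SeedSequence((seed, patient.id, 1000 + tag)))
    grades = model.sample_path(rel_dec, rng)
    return AEGradeSeries(ae=ae, times=days, grades=grades)


# ---------------------------------------------------------------------------
# CTCAE v3.0 grading
# ---------------------------------------------------------------------------

# descending cut points; grade = number of cuts at or above the value
_CTCAE_LOW = {
    "neutropenia": (2.0, 1.5, 1.0, 0.5),        # ANC, 1e9 cells/L (LLN 2.0)
    "thrombocytopenia": (150.0, 75.0, 50.0, 25.0),  # platelets, 1e9 cells/L
}
# ascending cut points for values graded high
_CTCAE_HIGH = {
    "hypertension": (90.0, 100.0, 110.0, 120.0),    # dBP, mmHg
}


def grade_ae(value: float, ae: str) -> int:
    """CTCAE v3.0 grade for a laboratory/vital value.

    A value exactly on a cut point maps to the more severe grade.
    """
    if ae in _CTCAE_LOW:
        if value <= 0:
            raise ValueError("lab value must be > 0")
        cuts = _CTCAE_LOW[ae]
        return int(sum(value <= c for c in cuts))
    if ae in _CTCAE_HIGH:
        cuts = _CTCAE_HIGH[ae]
        return int(sum(value >= c for c in cuts))
    raise ValueError(f"unknown AE {ae!r}")


def grade_array(values: np.ndarray, ae: str) -> np.ndarray:
    """Vectorized CTCAE grading (same cut/tie rules as :func:`grade_ae`)."""
    v = np.asarray(values, float)
    if ae in _CTCAE_LOW:
        cuts = _CTCAE_LOW[ae]
        return sum((v <= c).astype(np.int8) for c in cuts)
    if ae in _CTCAE_HIGH:
        cuts = _CTCAE_HIGH[ae]
        return sum((v >= c).astype(np.int8) for c in cuts)
    raise ValueError(f"unknown AE {ae!r}")


def grade_series(series: BiomarkerSeries, ae: str) -> AEGradeSeries:
    grades = np.array([grade_ae(float(v), ae) for v in series.values])
    return AEGradeSeries(ae=ae, times=series.times, grades=grades)


# ---------------------------------------------------------------------------
# hazard covariate transforms
# ---------------------------------------------------------------------------

def scaled_anc(value):
    """Scaled absolute ANC change: (ANC - 5)/5, population baseline 5e9/L."""
    return (np.asarray(value, float) - ANC_POPULATION_BASELINE) / ANC_POPULATION_BASELINE


def rel_change(value, baseline):
    """Relative change from individual baseline: (x - base)/base."""
    if baseline == 0:
        raise ZeroDivisionError("zero baseline")
    return (np.asarray(value, float) - baseline) / baseline


def covariate_transform(series: BiomarkerSeries, t: float) -> float:
    """Hazard covariate value at time t for a biomarker series."""
    if t < series.times[0] or t > series.times[-1]:
        raise ValueError("t outside series span")
    v = float(np.interp(t, series.times, series.values))
    if series.name == "anc":
        return float(scaled_anc(v))
    if series.name in ("dbp", "svegfr3", "skit"):
        return float(rel_change(v, series.baseline))
    raise ValueError(f"no transform defined for {series.name!r}")


# ---------------------------------------------------------------------------
# residual error
# ---------------------------------------------------------------------------

def apply_residual_error(values: np.ndarray, channel: str, params: ParameterSet,
                         rng: np.random.Generator) -> np.ndarray:
    """y = IPRED*(1 + eps_prop) + eps_add, eps ~ Normal(0, sigma)."""
    spec = params.residual_errors[channel]
    values = np.asarray(values, float)
    y = values * (1.0 + rng.normal(0.0, spec["proportional"], values.shape))
    if spec["additive"] > 0:
        y = y + rng.normal(0.0, spec["additive"], values.shape)
    return y
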