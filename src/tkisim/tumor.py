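"""Tumor size (SLD) dynamics and progression detection.

Growth-inhibition model of Claret type with saturating growth: logistic
net growth toward a carrying capacity ``tum_tmax`` plus a first-order kill
term driven by the framework's response markers,

``dT/dt = kg*T*(1 - T/Tmax) - E(t) * exp(-lambda_res * t) * T``

where ``E(t)`` sums the kill contributions (relative sVEGFR-3 decrease,
relative sKIT decrease, daily AUC for sunitinib; sVEGFR-3 only for
axitinib) and the exponential factor describes appearance of resistance.
With the drive held piecewise-constant on the grid the equation is a
Bernoulli ODE with a closed-form per-step solution, so the update is exact
up to the within-step variation of the resistance factor (evaluated at the
step midpoint).

Progression is operationalized RECIST-1.1-style: first time SLD rises at
least 20% and at least 5 mm above the running nadir (both configurable).
It is evaluated continuously on the simulation grid since it feeds the
dropout and OS hazards rather than imaging-visit decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biomarkers import BiomarkerSeries, _drive_on_grid
from .params import SUNITINIB, ParameterSet
from .population import VirtualPatient


@dataclass
class TumorTrajectory:
    times: np.ndarray      # h
    sld: np.ndarray        # mm
    nadir: np.ndarray      # running minimum of sld, mm
    progressed: bool
    progression_time: float | None  # h


@dataclass(frozen=True)
class ProgressionRule:
    rel_increase: float = 0.20  # fraction above nadir
    abs_increase: float = 5.0   # mm above nadir


def kill_effect(drivers: dict, params: ParameterSet,
                patient: VirtualPatient, times: np.ndarray) -> np.ndarray:
    """Total kill-rate contribution E(t) on ``times`` (1/h).

    A single kill-scale eta (on ``tum_kv3``) multiplies all drug-effect
    terms, modeling shared inter-individual drug sensitivity.
    """
    scale = math.exp(patient.etas.get("tum_kv3", 0.0))
    E = np.zeros_like(times, dtype=float)
    v3: BiomarkerSeries = drivers["svegfr3"]
    rel_dec = np.maximum(0.0, -(np.interp(times, v3.times, v3.values) - v3.baseline)
                         / v3.baseline)
    E += params["tum_kv3"] * scale * rel_dec
    if params.drug == SUNITINIB:
        if "skit" in drivers:
            sk: BiomarkerSeries = drivers["skit"]
            dec = np.maximum(0.0, -(np.interp(times, sk.times, sk.values) - sk.baseline)
                             / sk.baseline)
            E += params["tum_kskit"] * scale * dec
        if "auc" in drivers:
            t_a, auc = _drive_on_grid(drivers["auc"])
            auc_t = np.interp(times, t_a, auc) if t_a.size > 1 else np.full_like(times, auc[0])
            E += params["tum_kauc_max"] * scale * auc_t / (params["tum_auc50"] + auc_t)
    return E


def bernoulli_step(T, a, b, dt):
    """Exact step of dT/dt = a*T - b*T^2 over dt (a, b constant; b >= 0)."""
    T = np.asarray(T, float)
    a = np.asarray(a, float)
    ea = np.exp(a * dt)
    small = np.abs(a) < 1e-12
    denom = np.where(small, 1.0 + b * T * dt, a + b * T * (ea - 1.0))
    numer = np.where(small, T, a * T * ea)
    return numer / denom


def simulate_tumor(drivers: dict, params: ParameterSet, patient: VirtualPatient,
                   grid: np.ndarray | None = None,
                   rule: ProgressionRule = ProgressionRule()) -> TumorTrajectory:
    """Simulate SLD for one patient on ``grid`` (defaults to the sVEGFR-3 grid)."""
    if patient.baseline_tumor <= 0:
        raise ValueError("baseline tumor size must be > 0")
    times = np.asarray(grid, float) if grid is not None else drivers["svegfr3"].times
    kg = patient.individual(params, "tum_kg")
    lam = params["tum_lambda_res"]
    b = kg / params["tum_tmax"]
    E = kill_effect(drivers, params, patient, times)

    sld = np.empty_like(times, dtype=float)
    sld[0] = patient.baseline_tumor
    for i in range(1, times.size):
        t0, t1 = times[i - 1], times[i]
        dt = t1 - t0
        res = math.exp(-lam * 0.5 * (t0 + t1)) if lam > 0 else 1.0
        a = kg - E[i - 1] * res
        sld[i] = float(bernoulli_step(sld[i - 1], a, b, dt))
    nadir = np.minimum.accumulate(sld)
    traj = TumorTrajectory(times=times, sld=sld, nadir=nadir,
                           progressed=False, progression_time=None)
    tprog = detect_progression(traj, rule)
    traj.progressed = tprog is not None
    traj.progression_time = tprog
    return traj


def detect_progression(traj: TumorTrajectory,
                       rule: ProgressionRule = ProgressionRule()) -> float | None:
    """First time SLD exceeds the nadir-based progression rule, or None.

    Growth is measured from the running nadir *before* the current point,
    so a flat trajectory never progresses.
    """
    nadir = np.minimum.accumulate(traj.sld)
    hit = (traj.sld >= (1.0 + rule.rel_increase) * nadir) & \
          (traj.sld - nadir >= rule.abs_increase)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(traj.times[0])
    # refine crossing within the step by log-linear interpolation
    thr = max((1.0 + rule.rel_increase) * nadir[i - 1],
              nadir[i - 1] + rule.abs_increase)
    s0, s1 = traj.sld[i - 1], traj.sld[i]
    if s1 > s0 and s0 < thr <= s1:
        f = (math.log(thr) - math.log(s0)) / (math.log(s1) - math.log(s0))
        return float(traj.times[i - 1] + f * (traj.times[i] - traj.times[i - 1]))
    return float(traj.times[i])
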