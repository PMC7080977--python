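"""Pharmacokinetics: linear compartmental models under arbitrary dosing.

Sunitinib is modeled together with its active metabolite SU12662 (one
disposition compartment each, first-order absorption, fraction ``fm`` of
parent clearance forming metabolite); axitinib with a single disposition
compartment. All kinetics are linear, so the system ``dx/dt = A x`` is
propagated exactly with matrix exponentials between dose events, which are
handled as bolus state resets into the absorption compartment.

Individual parameters are typical value x ``exp(eta)`` with allometric
weight scaling on clearances and volumes. Amounts are in mg, volumes in L;
concentrations are reported in ng/ml (mg/L x 1000). The sunitinib ``total``
concentration (parent + SU12662) is the therapeutic-drug-monitoring metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import AXITINIB, SUNITINIB, ParameterSet
from .population import VirtualPatient


@dataclass(frozen=True)
class DoseEvent:
    time: float    # h
    amount: float  # mg

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass
class ConcentrationProfile:
    times: np.ndarray            # h
    parent: np.ndarray           # ng/ml
    metabolite: np.ndarray | None  # ng/ml (sunitinib only)
    total: np.ndarray            # ng/ml; parent + metabolite for sunitinib


@dataclass
class ExposureMetrics:
    auc_daily: np.ndarray        # ng*h/ml per 24 h window
    auc_windows: np.ndarray      # window start times, h
    ctrough: np.ndarray          # ng/ml at pre-dose times
    ctrough_times: np.ndarray    # h


def individual_pk_params(patient: VirtualPatient, params: ParameterSet) -> dict[str, float]:
    """Individual PK constants with allometric weight scaling and etas."""
    wt = (patient.weight / params["wt_ref"])
    f_cl = wt ** params["wt_exp_cl"]
    f_v = wt ** params["wt_exp_v"]
    ind = lambda name, f: patient.individual(params, name) * f
    if params.drug == SUNITINIB:
        return {
            "ka": patient.individual(params, "ka"),
            "cl_parent": ind("cl_parent", f_cl),
            "v_parent": ind("v_parent", f_v),
            "fm": params["fm"],
            "cl_met": ind("cl_met", f_cl),
            "v_met": ind("v_met", f_v),
        }
    return {
        "ka": patient.individual(params, "ka"),
        "cl": ind("cl", f_cl),
        "v": ind("v", f_v),
    }


def pk_system(patient: VirtualPatient, params: ParameterSet
              ) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, obs) for the linear system.

    ``A`` is the rate matrix over compartment amounts (gut first), ``obs``
    maps amounts to concentrations in ng/ml, one row per observed species
    (parent [, metabolite]).
    """
    p = individual_pk_params(patient, params)
    ka = p["ka"]
    if params.drug == SUNITINIB:
        kp = p["cl_parent"] / p["v_parent"]
        km = p["cl_met"] / p["v_met"]
        A = np.array([[-ka, 0.0, 0.0],
                      [ka, -kp, 0.0],
                      [0.0, p["fm"] * kp, -km]])
        obs = np.array([[0.0, 1000.0 / p["v_parent"], 0.0],
                        [0.0, 0.0, 1000.0 / p["v_met"]]])
    else:
        ke = p["cl"] / p["v"]
        A = np.array([[-ka, 0.0],
                      [ka, -ke]])
        obs = np.array([[0.0, 1000.0 / p["v"]]])
    return A, obs


def default_grid(regimen: list[DoseEvent], horizon: float,
                 fine: float = 1.0, coarse: float = 6.0,
                 fine_span: float = 72.0) -> np.ndarray:
    """Output grid: ``fine`` steps for ``fine_span`` h after any dose-amount
    change, ``coarse`` steps elsewhere."""
    changes = [0.0]
    last = None
    for d in sorted(regimen, key=lambda d: d.time):
        if (last is None or d.amount != last) and d.time < horizon:
            changes.append(d.time)
            last = d.amount
    pts = set(np.round(np.arange(0.0, horizon + 1e-9, coarse), 9))
    for c in changes:
        hi = min(c + fine_span, horizon)
        pts |= set(np.round(np.arange(c, hi + 1e-9, fine), 9))
    pts.add(float(horizon))
    return np.array(sorted(pts))


def simulate_pk(patient: VirtualPatient, regimen: list[DoseEvent],
                params: ParameterSet, grid: np.ndarray) -> ConcentrationProfile:
    """Exact linear-kinetics solution on ``grid`` under ``regimen``."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    doses = sorted(regimen, key=lambda d: d.time)
    for d in doses:
        if d.amount < 0:
            raise ValueError("negative dose")
    A, obs = pk_system(patient, params)
    n = A.shape[0]
    x = np.zeros(n)
    prop_cache: dict[float, np.ndarray] = {}

    def step_to(x, t0, t1):
        dt = t1 - t0
        if dt == 0:
            return x
        key = round(dt, 12)
        P = prop_cache.get(key)
        if P is None:
            P = expm(A * dt)
            prop_cache[key] = P
        return P @ x

    events = [(d.time, d.amount) for d in doses]
    out = np.zeros((obs.shape[0], grid.size))
    t = grid[0]
    ei = 0
    # apply doses at or before grid start
    while ei < len(events) and events[ei][0] <= t:
        if events[ei][0] < t:
            raise ValueError("dose before grid start")
        x[0] += events[ei][1]
        ei += 1
    out[:, 0] = obs @ x
    for gi in range(1, grid.size):
        tg = grid[gi]
        while ei < len(events) and events[ei][0] <= tg:
            te, amt = events[ei]
            x = step_to(x, t, te)
            t = te
            x[0] += amt
            ei += 1
        x = step_to(x, t, tg)
        t = tg
        out[:, gi] = obs @ x

    parent = out[0]
    met = out[1] if out.shape[0] > 1 else None
    total = parent + met if met is not None else parent.copy()
    return ConcentrationProfile(times=grid, parent=parent, metabolite=met, total=total)


def compute_exposure(profile: ConcentrationProfile, dosing_interval: float,
                     which: str = "total") -> ExposureMetrics:
    """AUC per 24 h window (trapezoid on the simulation grid) and C_trough
    read at end-of-interval (pre-dose) time points."""
    t = profile.times
    c = getattr(profile, which)
    span = t[-1] - t[0]
    if dosing_interval > span:
        raise ValueError("dosing interval longer than profile span")
    # daily AUC windows
    starts = np.arange(t[0], t[-1] - 24.0 + 1e-9, 24.0)
    aucs = np.empty(starts.size)
    for i, s in enumerate(starts):
        m = (t >= s - 1e-9) & (t <= s + 24.0 + 1e-9)
        aucs[i] = np.trapezoid(c[m], t[m])
    # troughs at multiples of the dosing interval (just before next dose)
    ct_times = np.arange(t[0] + dosing_interval, t[-1] + 1e-9, dosing_interval)
    ctrough = np.interp(ct_times, t, c)
    return ExposureMetrics(auc_daily=aucs, auc_windows=starts,
                           ctrough=ctrough, ctrough_times=ct_times)


def regimen_to_frame(regimen: list[DoseEvent]):
    import pandas as pd
    return pd.DataFrame({"time": [d.time for d in regimen],
                         "amount": [d.amount for d in regimen]})


def regimen_from_frame(df) -> list[DoseEvent]:
    return [DoseEvent(float(r.time), float(r.amount)) for r in df.itertuples()]
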