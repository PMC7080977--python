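"""Virtual patient populations.

Generates virtual GIST (sunitinib) or mRCC (axitinib) patients: covariates
sampled from the stated population distributions and log-normal
inter-individual random effects (etas) with the variances of the active
:class:`~tkisim.params.ParameterSet`.

Distributions
-------------
* weight ~ Normal(73.5, 18.7) kg for the GIST population
  (Normal(76.7, 11.6) for mRCC), truncated to [36, 185] kg by rejection;
* baseline tumor size (SLD) ~ LogNormal with *arithmetic* mean 182.7 mm and
  SD 134.2 mm (log-scale parameters obtained by moment matching), truncated
  to [29, 822] mm by rejection;
* etas ~ independent Normal(0, omega^2) per parameter.

Each patient draws from a dedicated RNG substream keyed on (seed, id), so
enlarging a population never perturbs earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AXITINIB, SUNITINIB, ParameterSet

WEIGHT_BOUNDS = (36.0, 185.0)
TUMOR_BOUNDS = (29.0, 822.0)
WEIGHT_DIST = {SUNITINIB: (73.5, 18.7), AXITINIB: (76.7, 11.6)}
TUMOR_MEAN, TUMOR_SD = 182.7, 134.2


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) on the log scale for given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _rejection_sample(rng: np.random.Generator, draw, lo: float, hi: float,
                      max_tries: int = 10_000) -> float:
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("rejection sampling failed to land in range")


@dataclass
class VirtualPatient:
    """Covariates plus sampled random effects; the unit of simulation."""

    id: int
    drug: str
    weight: float                     # kg
    baseline_tumor: float             # mm SLD
    etas: dict[str, float]            # log-scale random effects
    baseline_biomarkers: dict[str, float] = field(default_factory=dict)
    #: entropy stub for per-patient downstream RNG streams
    seed_key: tuple[int, int] = (0, 0)

    def individual(self, params: ParameterSet, name: str) -> float:
        """Individual parameter value: typical x exp(eta)."""
        return params[name] * math.exp(self.etas.get(name, 0.0))


def _baselines(drug: str, params: ParameterSet, etas: dict[str, float]) -> dict[str, float]:
    """Baseline biomarkers = each submodel's steady state under zero drug.

    For the turnover models X(0) = k_in/k_out scaled by the patient's
    baseline eta, i.e. typical baseline x exp(eta).
    """
    e = lambda k: math.exp(etas.get(k, 0.0))
    out = {"sVEGFR3_0": params["base_svegfr3"] * e("base_svegfr3"),
           "dBP_0": params["base_dbp"] * e("base_dbp")}
    if drug == SUNITINIB:
        out["sKIT_0"] = params["base_skit"] * e("base_skit")
        out["ANC_0"] = params["base_anc"] * e("base_anc")
        out["platelet_0"] = params["base_plt"] * e("base_plt")
    return out


def sample_population(n: int, drug: str, seed: int,
                      params: ParameterSet) -> list[VirtualPatient]:
    """Sample ``n`` virtual patients for ``drug``; reproducible under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.drug != drug:
        raise ValueError(f"parameter set is for {params.drug!r}, not {drug!r}")
    w_mean, w_sd = WEIGHT_DIST[drug]
    mu, sigma = lognormal_params_from_moments(TUMOR_MEAN, TUMOR_SD)
    eta_names = sorted(params.iiv)
    eta_sds = np.sqrt([params.iiv[k] for k in eta_names])

    patients = []
    for pid in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, pid)))
        weight = _rejection_sample(
            rng, lambda r: r.normal(w_mean, w_sd), *WEIGHT_BOUNDS)
        tumor = _rejection_sample(
            rng, lambda r: math.exp(r.normal(mu, sigma)), *TUMOR_BOUNDS)
        eta_vals = rng.normal(0.0, eta_sds)
        etas = dict(zip(eta_names, map(float, eta_vals)))
        patients.append(VirtualPatient(
            id=pid, drug=drug, weight=weight, baseline_tumor=tumor,
            etas=etas, baseline_biomarkers=_baselines(drug, params, etas),
            seed_key=(seed, pid)))
    return patients


# -- tabular export / import -------------------------------------------------

def population_to_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {"id": p.id, "drug": p.drug, "weight": p.weight,
               "baseline_tumor": p.baseline_tumor,
               "seed": p.seed_key[0], "sub": p.seed_key[1]}
        row.update({f"eta_{k}": v for k, v in p.etas.items()})
        row.update({f"base_{k}": v for k, v in p.baseline_biomarkers.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def save_population(patients: list[VirtualPatient], path: str | Path) -> None:
    population_to_frame(patients).to_csv(path, index=False)


def load_population(path: str | Path) -> list[VirtualPatient]:
    df = pd.read_csv(path)
    patients = []
    for _, r in df.iterrows():
        etas = {c[4:]: float(r[c]) for c in df.columns if c.startswith("eta_")}
        bases = {c[5:]: float(r[c]) for c in df.columns if c.startswith("base_")}
        patients.append(VirtualPatient(
            id=int(r["id"]), drug=str(r["drug"]), weight=float(r["weight"]),
            baseline_tumor=float(r["baseline_tumor"]), etas=etas,
            baseline_biomarkers=bases, seed_key=(int(r["seed"]), int(r["sub"]))))
    return patients
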