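"""Parameter sets driving the simulation frameworks.

A :class:`ParameterSet` is the single source of truth for every structural
model constant of one drug's framework: fixed effects, inter-individual
variability (IIV) variances of log-normal random effects, residual-error
magnitudes, and per-parameter provenance strings.

Two parameter files are bundled per drug: ``<drug>_reference.yaml`` (model
structures following the published source models, representative magnitudes)
and ``<drug>_fallback.yaml`` (documented round numbers, same schema).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SUNITINIB = "sunitinib"
AXITINIB = "axitinib"
DRUGS = (SUNITINIB, AXITINIB)

#: Required fixed-effect keys per drug. Deleting any one of these from a
#: config must produce a validation error naming it.
REQUIRED_FIXED: dict[str, tuple[str, ...]] = {
    SUNITINIB: (
        "ka", "cl_parent", "v_parent", "fm", "cl_met", "v_met",
        "wt_ref", "wt_exp_cl", "wt_exp_v",
        "base_svegfr3", "mrt_svegfr3_h", "imax_svegfr3", "ic50_svegfr3",
        "base_skit", "mrt_skit_h", "imax_skit", "ic50_skit",
        "base_anc", "mtt_anc_h", "gamma_anc", "slope_anc",
        "base_plt", "mtt_plt_h", "gamma_plt", "emax_plt", "auc50_plt",
        "base_dbp", "mrt_dbp_h", "slope_dbp",
        "fat_int_g1", "fat_int_g2", "fat_int_g3", "fat_beta_v3", "fat_kappa",
        "hfs_int_g1", "hfs_int_g2", "hfs_int_g3", "hfs_beta_v3", "hfs_kappa",
        "tum_kg", "tum_kv3", "tum_kskit", "tum_kauc_max", "tum_auc50", "tum_lambda_res", "tum_tmax",
        "os_tad_weib_scale_h", "os_tad_weib_shape",
        "os_tad_beta_dbp", "os_tad_beta_anc", "os_tad_beta_bsld",
        "os_bad_weib_scale_h", "os_bad_weib_shape",
        "os_bad_beta_v3", "os_bad_beta_bsld", "bsld_ref",
        "drop_lambda_h", "drop_beta_prog", "drop_beta_sld",
    ),
    AXITINIB: (
        "ka", "cl", "v", "wt_ref", "wt_exp_cl", "wt_exp_v",
        "base_svegfr3", "mrt_svegfr3_h", "imax_svegfr3", "ic50_svegfr3",
        "base_dbp", "mrt_dbp_h", "emax_dbp", "ec50_dbp",
        "tum_kg", "tum_kv3", "tum_lambda_res", "tum_tmax",
        "os_weib_scale_h", "os_weib_shape", "os_beta_sld", "os_beta_prog",
        "drop_lambda_h", "drop_beta_prog", "drop_beta_sld", "drop_beta_auc",
    ),
}

#: Residual-error channels that must be present per drug.
REQUIRED_RESIDUAL: dict[str, tuple[str, ...]] = {
    SUNITINIB: ("conc", "svegfr3", "skit", "anc", "platelets", "dbp"),
    AXITINIB: ("conc", "svegfr3", "dbp"),
}

# Strictly positive parameters: rate constants, clearances, volumes,
# baselines, turnover times, potencies, hazard scales.
_POSITIVE_PREFIXES = ("ka", "cl", "v", "base_", "mrt_", "mtt_", "ic50", "ec50",
                      "wt_ref", "gamma_")
_POSITIVE_EXACT = {"fm", "cl_parent", "v_parent", "cl_met", "v_met", "cl", "v",
                   "os_tad_weib_scale_h", "os_tad_weib_shape",
                   "os_bad_weib_scale_h", "os_bad_weib_shape",
                   "os_weib_scale_h", "os_weib_shape",
                   "drop_lambda_h", "tum_kg", "bsld_ref"}


class ParameterValidationError(ValueError):
    """Raised when a parameter config violates the schema; lists offenders."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid parameter set:\n  - " + "\n  - ".join(problems))


def _is_positive_required(name: str) -> bool:
    if name in _POSITIVE_EXACT:
        return True
    return any(name == p or name.startswith(p) for p in _POSITIVE_PREFIXES)


@dataclass
class ParameterSet:
    """All constants of one drug's coupled PK-PD-survival framework."""

    drug: str
    fixed_effects: dict[str, float]
    iiv: dict[str, float]
    residual_errors: dict[str, dict[str, float]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.fixed_effects[name]

    def validate(self) -> None:
        problems: list[str] = []
        if self.drug not in DRUGS:
            raise ParameterValidationError([f"unknown drug {self.drug!r}"])
        for key in REQUIRED_FIXED[self.drug]:
            if key not in self.fixed_effects:
                problems.append(f"missing required fixed effect: {key}")
        for key, value in self.fixed_effects.items():
            if _is_positive_required(key) and not value > 0:
                problems.append(f"fixed effect {key} must be > 0, got {value}")
        for key, var in self.iiv.items():
            if var < 0:
                problems.append(f"iiv variance {key} must be >= 0, got {var}")
        for channel in REQUIRED_RESIDUAL[self.drug]:
            if channel not in self.residual_errors:
                problems.append(f"missing residual-error channel: {channel}")
        for channel, spec in self.residual_errors.items():
            for part in ("proportional", "additive"):
                if part not in spec:
                    problems.append(f"residual error {channel} missing {part!r}")
                elif spec[part] < 0:
                    problems.append(
                        f"residual error {channel}.{part} must be >= 0, got {spec[part]}")
        if problems:
            raise ParameterValidationError(problems)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "fixed_effects": dict(self.fixed_effects),
            "iiv": dict(self.iiv),
            "residual_errors": {k: dict(v) for k, v in self.residual_errors.items()},
            "provenance": dict(self.provenance),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "ParameterSet":
        ps = cls(
            drug=raw.get("drug", ""),
            fixed_effects={k: float(v) for k, v in raw.get("fixed_effects", {}).items()},
            iiv={k: float(v) for k, v in raw.get("iiv", {}).items()},
            residual_errors={k: {kk: float(vv) for kk, vv in v.items()}
                             for k, v in raw.get("residual_errors", {}).items()},
            provenance=dict(raw.get("provenance", {})),
        )
        ps.validate()
        return ps


def load_parameter_set(path: str | Path, drug: str | None = None) -> ParameterSet:
    """Load and validate a parameter config file.

    Parameters
    ----------
    path
        YAML file with ``drug``, ``fixed_effects``, ``iiv``,
        ``residual_errors`` and ``provenance`` sections.
    drug
        If given, the file's drug section must match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterValidationError(["config did not parse to a mapping"])
    if drug is not None and raw.get("drug") != drug:
        raise ParameterValidationError(
            [f"expected drug {drug!r}, file declares {raw.get('drug')!r}"])
    return ParameterSet.from_dict(raw)


def default_parameter_set(drug: str, which: str = "reference") -> ParameterSet:
    """Load a bundled parameter set (``which`` in {'reference', 'fallback'})."""
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    if which not in ("reference", "fallback"):
        raise ValueError(f"unknown parameter bundle {which!r}")
    res = importlib.resources.files("tkisim.data") / f"{drug}_{which}.yaml"
    with importlib.resources.as_file(res) as p:
        return load_parameter_set(p, drug=drug)
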