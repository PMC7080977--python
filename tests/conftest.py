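import copy

import numpy as np
import pytest

import tkisim as tk


@pytest.fixture(scope="session")
def sun_params():
    return tk.default_parameter_set(tk.SUNITINIB)


@pytest.fixture(scope="session")
def axi_params():
    return tk.default_parameter_set(tk.AXITINIB)


@pytest.fixture(scope="session")
def sun_pop(sun_params):
    return tk.sample_population(20, tk.SUNITINIB, 123, sun_params)


@pytest.fixture(scope="session")
def axi_pop(axi_params):
    return tk.sample_population(20, tk.AXITINIB, 123, axi_params)


@pytest.fixture(scope="session")
def typical_patient(sun_params):
    """A patient with all etas zero: the population-typical individual."""
    p = tk.sample_population(1, tk.SUNITINIB, 5, sun_params)[0]
    return tk.VirtualPatient(
        id=0, drug=tk.SUNITINIB, weight=sun_params["wt_ref"],
        baseline_tumor=182.7, etas={k: 0.0 for k in p.etas},
        baseline_biomarkers={k: v for k, v in {
            "sVEGFR3_0": sun_params["base_svegfr3"],
            "sKIT_0": sun_params["base_skit"],
            "ANC_0": sun_params["base_anc"],
            "dBP_0": sun_params["base_dbp"],
            "platelet_0": sun_params["base_plt"]}.items()},
        seed_key=(5, 0))


def make_inert(params):
    """Copy of a parameter set with every drug effect switched off and
    categorical AEs made impossible: pure natural history."""
    ps = copy.deepcopy(params)
    fe = ps.fixed_effects
    for k in ("imax_svegfr3", "imax_skit", "slope_anc", "slope_dbp",
              "emax_plt", "emax_dbp", "tum_kv3", "tum_kskit", "tum_kauc_max"):
        if k in fe:
            fe[k] = 0.0
    for k in list(fe):
        if k.startswith(("fat_int", "hfs_int")):
            fe[k] = -60.0 - {"1": 0, "2": 1, "3": 2}[k[-1]]
    return ps


@pytest.fixture(scope="session")
def inert_sun_params(sun_params):
    return make_inert(sun_params)


@pytest.fixture(scope="session")
def inert_axi_params(axi_params):
    return make_inert(axi_params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
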