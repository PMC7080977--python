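import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tkisim as tk
from tkisim.biomarkers import (ANC_POPULATION_BASELINE, CategoricalAEModel,
                               grade_array, indirect_step,
                               myelosuppression_drive, transit_steady_state,
                               transit_step)


# ---------------------------------------------------------------------------
# turnover (indirect-response) models
# ---------------------------------------------------------------------------

def test_zero_drug_keeps_biomarker_at_baseline(typical_patient, sun_params):
    t = np.arange(0.0, 2000.0, 2.0)
    driver = (t, np.zeros_like(t))
    for name in ("svegfr3", "skit"):
        series = tk.simulate_indirect_response(driver, sun_params,
                                               typical_patient, name)
        assert np.allclose(series.values, series.baseline)


def test_full_inhibition_decays_exponentially(typical_patient, sun_params):
    """With effect == 1 the production shuts off: X(t) = X0 exp(-kout t)."""
    t = np.arange(0.0, 1000.0, 2.0)
    driver = (t, np.full_like(t, 1e12))   # conc >> IC50 -> effect ~ 1
    series = tk.simulate_indirect_response(driver, sun_params,
                                           typical_patient, "svegfr3")
    kout = 1.0 / sun_params["mrt_svegfr3_h"]
    expected = series.baseline * np.exp(-kout * t)
    assert np.allclose(series.values, expected, rtol=1e-6)


def test_piecewise_constant_drive_matches_analytic_solution(typical_patient,
                                                            sun_params):
    """Step input: the trajectory matches the sequential closed-form linear
    ODE solution to within 0.1% (it is exact by construction)."""
    t = np.arange(0.0, 1200.0, 4.0)
    conc = np.where(t < 400, 0.0, np.where(t < 800, 100.0, 20.0))
    series = tk.simulate_indirect_response((t, conc), sun_params,
                                           typical_patient, "svegfr3")
    # independent oracle: closed-form segment-by-segment solution
    base = series.baseline
    kout = 1.0 / sun_params["mrt_svegfr3_h"]
    ic50 = sun_params["ic50_svegfr3"]
    x = np.empty_like(t)
    x[0] = base
    for i in range(1, t.size):
        eff = conc[i - 1] / (ic50 + conc[i - 1])
        xss = base * (1 - eff)
        x[i] = xss + (x[i - 1] - xss) * np.exp(-kout * (t[i] - t[i - 1]))
    assert np.allclose(series.values, x, rtol=1e-3)


def test_dbp_rises_under_positive_drive(typical_patient, sun_params):
    t = np.arange(0.0, 2000.0, 4.0)
    series = tk.simulate_indirect_response((t, np.full_like(t, 900.0)),
                                           sun_params, typical_patient, "dbp")
    stim = sun_params["slope_dbp"] * 900.0
    assert series.values[-1] == pytest.approx(series.baseline * (1 + stim),
                                              rel=1e-3)


def test_nonpositive_turnover_rejected(typical_patient, sun_params):
    bad = tk.ParameterSet.from_dict(sun_params.to_dict())
    t = np.arange(0.0, 10.0, 1.0)
    bad.fixed_effects["mrt_svegfr3_h"] = 100.0
    bad.fixed_effects["base_svegfr3"] = 50.0
    patient = tk.VirtualPatient(id=0, drug=tk.SUNITINIB, weight=70,
                                baseline_tumor=100,
                                etas={"base_svegfr3": -1e9})  # baseline -> 0
    with pytest.raises(ValueError):
        tk.simulate_indirect_response((t, np.zeros_like(t)), bad, patient,
                                      "svegfr3")


# ---------------------------------------------------------------------------
# transit-compartment myelosuppression
# ---------------------------------------------------------------------------

def test_no_drug_keeps_cell_counts_at_baseline(typical_patient, sun_params):
    t = np.arange(0.0, 3000.0, 2.0)
    v3_flat = tk.BiomarkerSeries("svegfr3", t, np.full_like(
        t, sun_params["base_svegfr3"]), sun_params["base_svegfr3"])
    anc = tk.simulate_myelosuppression(v3_flat, sun_params, typical_patient, "anc")
    assert anc.baseline == pytest.approx(ANC_POPULATION_BASELINE)
    assert np.allclose(anc.values, anc.baseline, rtol=1e-9)


def test_drug_on_produces_nadir_then_rebound(typical_patient, sun_params):
    """Finite exposure: circulating count dips after a transit delay and
    recovers (with overshoot) after washout."""
    t = np.arange(0.0, 6000.0, 2.0)
    base = sun_params["base_svegfr3"]
    v3 = np.where(t < 2000, 0.35 * base, base)  # strong suppression, then off
    series = tk.BiomarkerSeries("svegfr3", t, v3, base)
    anc = tk.simulate_myelosuppression(series, sun_params, typical_patient, "anc")
    i_nadir = int(np.argmin(anc.values))
    assert 0 < anc.times[i_nadir] < 6000
    assert anc.values[i_nadir] < 0.95 * anc.baseline
    assert anc.values[-1] > anc.values[i_nadir]  # rebound


def test_long_run_state_matches_analytic_steady_state(typical_patient, sun_params):
    t = np.arange(0.0, 40_000.0, 4.0)
    base = sun_params["base_svegfr3"]
    v3 = tk.BiomarkerSeries("svegfr3", t, np.full_like(t, 0.6 * base), base)
    anc = tk.simulate_myelosuppression(v3, sun_params, typical_patient, "anc")
    _, effect = myelosuppression_drive(v3, sun_params, typical_patient, "anc")
    expected = transit_steady_state(anc.baseline, sun_params["gamma_anc"],
                                    float(effect[0]))
    assert anc.values[-1] == pytest.approx(expected, rel=1e-3)


def test_negative_transit_time_rejected(sun_params):
    patient = tk.VirtualPatient(id=0, drug=tk.SUNITINIB, weight=70,
                                baseline_tumor=100, etas={"mtt_anc_h": -1e9})
    t = np.arange(0.0, 10.0, 1.0)
    v3 = tk.BiomarkerSeries("svegfr3", t, np.full_like(t, 60.0), 60.0)
    with pytest.raises(ValueError):
        tk.simulate_myelosuppression(v3, sun_params, patient, "anc")


# ---------------------------------------------------------------------------
# ordered-categorical AEs
# ---------------------------------------------------------------------------

@given(x=st.floats(0, 3), prev=st.integers(0, 3),
       t1=st.floats(-8, 0), d2=st.floats(0.1, 5), d3=st.floats(0.1, 5),
       beta=st.floats(0, 5), kappa=st.floats(0, 5))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_cumulative_probabilities_non_increasing(x, prev, t1, d2, d3, beta, kappa):
    model = CategoricalAEModel([t1, t1 - d2, t1 - d2 - d3], beta, kappa)
    cum = model.cumulative_probs(x, prev)
    assert np.all(np.diff(cum) <= 1e-12)
    probs = model.grade_probs(x, prev)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(probs >= -1e-12)


def test_stationary_distribution_matches_long_run_sampling(sun_params, rng):
    model = CategoricalAEModel.from_params(sun_params, "hfs")
    x = 1.2  # strong driver so all grades are visited
    pi = model.stationary_distribution(x)
    path = model.sample_path(np.full(200_000, x), rng)
    freq = np.bincount(path, minlength=4) / path.size
    assert np.allclose(freq, pi, atol=0.01)


def test_sampled_transitions_match_transition_matrix(rng):
    model = CategoricalAEModel([-1.0, -2.5, -4.0], beta=1.0, kappa=0.8)
    x = 0.8
    P = model.transition_matrix(x)
    assert np.allclose(P.sum(axis=1), 1.0)
    n = 100_000
    for prev in range(4):
        draws = model.sample_path(np.full(1, x), rng)  # warm call
        counts = np.zeros(4)
        probs = model.grade_probs(x, prev)
        samples = rng.choice(4, size=n, p=probs)
        counts = np.bincount(samples, minlength=4)
        # binomial 95% bounds around the matrix row
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(counts / n - P[prev]) < 4 * se + 1e-4)


def test_categorical_path_reproducible_under_seed(typical_patient, sun_params):
    t = np.arange(0.0, 100 * 24.0, 24.0)
    base = sun_params["base_svegfr3"]
    driver = tk.BiomarkerSeries("svegfr3", t, np.full_like(t, 0.5 * base), base)
    a = tk.simulate_categorical_ae(driver, sun_params, typical_patient, "hfs", 5)
    b = tk.simulate_categorical_ae(driver, sun_params, typical_patient, "hfs", 5)
    c = tk.simulate_categorical_ae(driver, sun_params, typical_patient, "hfs", 6)
    assert np.array_equal(a.grades, b.grades)
    assert a.grades.max() <= 3
    assert not np.array_equal(a.grades, c.grades) or a.grades.sum() == 0


# ---------------------------------------------------------------------------
# CTCAE grading
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value, ae, grade", [
    (0.8, "neutropenia", 3),     # 0.5 <= ANC < 1.0 -> G3
    (2.5, "neutropenia", 0),
    (1.5, "neutropenia", 2),     # boundary -> more severe grade
    (0.5, "neutropenia", 4),
    (200.0, "thrombocytopenia", 0),
    (60.0, "thrombocytopenia", 2),
    (25.0, "thrombocytopenia", 4),
    (85.0, "hypertension", 0),
    (90.0, "hypertension", 1),   # boundary -> more severe grade
    (105.0, "hypertension", 2),
    (121.0, "hypertension", 4),
])
def test_ctcae_lookup(value, ae, grade):
    assert tk.grade_ae(value, ae) == grade


def test_grade_array_agrees_with_scalar_lookup(rng):
    vals = rng.uniform(0.1, 6.0, size=200)
    vec = grade_array(vals, "neutropenia")
    assert list(vec) == [tk.grade_ae(v, "neutropenia") for v in vals]


def test_unknown_ae_rejected():
    with pytest.raises(ValueError):
        tk.grade_ae(1.0, "nausea")


def test_nonpositive_lab_value_rejected():
    with pytest.raises(ValueError):
        tk.grade_ae(0.0, "neutropenia")


# ---------------------------------------------------------------------------
# hazard covariate transforms
# ---------------------------------------------------------------------------

def test_scaled_anc_change():
    assert tk.scaled_anc(4.0) == pytest.approx(-0.2)
    assert tk.scaled_anc(5.0) == 0.0


def test_relative_dbp_change():
    assert tk.rel_change(90.0, 80.0) == pytest.approx(0.125)


def test_transform_dispatch_and_identity_at_baseline():
    t = np.arange(0.0, 100.0, 1.0)
    v3 = tk.BiomarkerSeries("svegfr3", t, np.full_like(t, 60.0), 60.0)
    assert tk.covariate_transform(v3, 50.0) == 0.0
    anc = tk.BiomarkerSeries("anc", t, np.full_like(t, 4.0), 5.0)
    assert tk.covariate_transform(anc, 10.0) == pytest.approx(-0.2)


def test_zero_baseline_division_error():
    with pytest.raises(ZeroDivisionError):
        tk.rel_change(10.0, 0.0)
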