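import numpy as np
import pytest

import tkisim as tk
from tkisim.trial import AE_NAMES


def protocol(**kw):
    base = dict(drug=tk.SUNITINIB, schedule="CD", start_dose=37.5,
                dose_pool=tk.SUNITINIB_POOL, horizon_weeks=12)
    base.update(kw)
    return tk.Protocol(**base)


# ---------------------------------------------------------------------------
# protocol and calendar
# ---------------------------------------------------------------------------

def test_monitoring_calendar():
    assert tk.lab_days(300) == [15, 29, 43, 57, 85, 113, 197, 281]
    assert tk.lab_days(113)[-1] == 113


def test_protocol_validation():
    with pytest.raises(ValueError):
        protocol(start_dose=40.0)          # not in pool
    with pytest.raises(ValueError):
        protocol(dose_pool=(12.5, 25.0, 37.5))   # missing 0
    with pytest.raises(ValueError):
        protocol(adaptation="TDM")         # threshold required
    with pytest.raises(ValueError):
        protocol(schedule="QOD")


def test_drug_mismatch_rejected(sun_pop, axi_params):
    with pytest.raises(ValueError):
        tk.run_trial(sun_pop, protocol(), axi_params, seed=1)


# ---------------------------------------------------------------------------
# dose-decision rules (pure functions, every branch)
# ---------------------------------------------------------------------------

G0 = {ae: 0 for ae in AE_NAMES}


def grades(**kw):
    g = dict(G0)
    g.update(kw)
    return g


@pytest.mark.parametrize("gr, counters, withheld, pend, action, dose", [
    # no toxicity -> continue
    (grades(), {}, False, False, "continue", 37.5),
    # first G3 lab toxicity -> withhold, later resume same
    (grades(thrombocytopenia=3), {"thrombocytopenia": 1}, False, False,
     "withhold", 37.5),
    (grades(), {"thrombocytopenia": 1}, True, False, "resume_same", 37.5),
    # repeated G3 -> withhold with pending reduction, resume one level lower
    (grades(thrombocytopenia=3), {"thrombocytopenia": 2}, False, False,
     "withhold", 37.5),
    (grades(), {"thrombocytopenia": 2}, True, True, "resume_reduced", 25.0),
    # G4 on first occurrence -> reduction
    (grades(neutropenia=4), {"neutropenia": 1}, False, False, "withhold", 37.5),
    # fatigue/HFS severe bar is grade 2
    (grades(fatigue=2), {"fatigue": 1}, False, False, "withhold", 37.5),
    (grades(hfs=3), {"hfs": 1}, False, False, "withhold", 37.5),
    # grade 2 lab toxicity is tolerated
    (grades(neutropenia=2), {}, False, False, "continue", 37.5),
    # withheld but not yet recovered -> stay withheld
    (grades(neutropenia=2), {"neutropenia": 1}, True, False, "withhold", 37.5),
])
def test_toxicity_rule_branches(gr, counters, withheld, pend, action, dose):
    act, new_dose, _ = tk.apply_toxicity_rules(
        gr, counters, 37.5, tk.SUNITINIB_POOL, withheld=withheld,
        pending_reduction=pend)
    assert act == action
    assert new_dose == dose


def test_g4_first_occurrence_marks_pending_reduction():
    _, _, pend = tk.apply_toxicity_rules(
        grades(neutropenia=4), {"neutropenia": 1}, 37.5, tk.SUNITINIB_POOL)
    assert pend
    act, dose, pend2 = tk.apply_toxicity_rules(
        grades(), {"neutropenia": 1}, 37.5, tk.SUNITINIB_POOL,
        withheld=True, pending_reduction=True)
    assert act == "resume_reduced" and dose == 25.0 and not pend2


def test_dose_floor_is_zero():
    act, dose, _ = tk.apply_toxicity_rules(
        grades(), {"hfs": 3}, 12.5, tk.SUNITINIB_POOL, withheld=True,
        pending_reduction=True)
    assert dose == 0.0
    act, dose, _ = tk.apply_toxicity_rules(
        grades(), {"hfs": 4}, 0.0, tk.SUNITINIB_POOL, withheld=True,
        pending_reduction=True)
    assert dose == 0.0


@pytest.mark.parametrize("signal, adaptation, thr, dose, expected", [
    (40.0, "TDM", 50.0, 37.5, 50.0),     # sub-target trough -> step up
    (60.0, "TDM", 50.0, 37.5, 37.5),     # at/beyond target -> hold
    (0.30, "BAD_sVEGFR3", 0.25, 37.5, 37.5),  # 30% decrease >= 25% -> hold
    (0.10, "BAD_sVEGFR3", 0.25, 37.5, 50.0),  # small decrease -> step up
    (0.10, "TAD_ANC", 0.20, 50.0, 62.5),
    (0.05, "TAD_dBP", 0.125, 37.5, 50.0),
    (40.0, "TDM", 50.0, 75.0, 75.0),     # pool maximum: no step beyond
    (40.0, "TDM", 50.0, 37.5, 37.5),     # toxicity precedence (withheld)
])
def test_biomarker_rule_branches(signal, adaptation, thr, dose, expected):
    withheld = expected == dose and signal == 40.0 and dose == 37.5
    new = tk.apply_biomarker_rule(signal, adaptation, thr, dose,
                                  tk.SUNITINIB_POOL, withheld=withheld)
    assert new == expected


def test_biomarker_rule_optional_down_titration():
    assert tk.apply_biomarker_rule(0.5, "BAD_sVEGFR3", 0.25, 37.5,
                                   tk.SUNITINIB_POOL, allow_down=True) == 25.0


# ---------------------------------------------------------------------------
# engine behavior
# ---------------------------------------------------------------------------

def test_zero_toxicity_parameterization_keeps_start_dose(sun_pop, inert_sun_params):
    res = tk.run_trial(sun_pop, protocol(), inert_sun_params, seed=9)
    on_trt = res.dropout_time_h[:, None] / 24.0 > res.days[None, :-1]
    alive = res.death_time_h[:, None] / 24.0 > res.days[None, :-1]
    active = on_trt & alive
    assert np.all(res.dose_given[:, :-1][active] == 37.5)


def test_determinism_same_seed_identical_records(sun_pop, sun_params):
    a = tk.run_trial(sun_pop, protocol(), sun_params, seed=4)
    b = tk.run_trial(sun_pop, protocol(), sun_params, seed=4)
    assert np.array_equal(a.death_time_h, b.death_time_h)
    assert np.array_equal(a.dose_given, b.dose_given)
    for k in a.series:
        assert np.array_equal(a.series[k], b.series[k])


def test_all_administered_doses_come_from_the_pool(sun_pop, sun_params):
    res = tk.run_trial(sun_pop, protocol(horizon_weeks=24), sun_params, seed=4)
    amounts = np.unique(res.dose_given)
    assert set(np.round(amounts, 6)) <= set(tk.SUNITINIB_POOL)


def test_no_dosing_after_dropout_or_death(sun_pop, sun_params):
    res = tk.run_trial(sun_pop, protocol(horizon_weeks=60), sun_params, seed=4)
    for i in range(res.n):
        stop = min(res.dropout_time_h[i], res.death_time_h[i]) / 24.0
        if np.isfinite(stop):
            after = res.days > stop
            assert np.all(res.dose_given[i, after] == 0.0)


def test_zeroed_drug_effects_make_arms_identical_natural_history(
        sun_pop, inert_sun_params):
    """With all drug effects off, CD and QW arms share the same natural
    history and, under common random numbers, identical event times."""
    cd = tk.run_trial(sun_pop, protocol(horizon_weeks=24),
                      inert_sun_params, seed=2)
    qw = tk.run_trial(sun_pop, protocol(schedule="QW", start_dose=300.0,
                                        dose_pool=tk.SUNITINIB_POOL_HIGH,
                                        horizon_weeks=24),
                      inert_sun_params, seed=2)
    assert np.allclose(cd.death_time_h, qw.death_time_h, equal_nan=True)
    assert np.allclose(cd.dropout_time_h, qw.dropout_time_h, equal_nan=True)


def test_sunitinib_dropout_ignores_exposure(sun_pop, inert_sun_params):
    """Different regimens with identical tumor paths leave the dropout law
    unchanged (dropout depends on progression and size only)."""
    lo = tk.run_trial(sun_pop, protocol(start_dose=12.5, horizon_weeks=24),
                      inert_sun_params, seed=2)
    hi = tk.run_trial(sun_pop, protocol(start_dose=75.0, horizon_weeks=24),
                      inert_sun_params, seed=2)
    assert np.allclose(lo.dropout_time_h, hi.dropout_time_h, equal_nan=True)


def test_grid_refinement_leaves_outcomes_stable(sun_pop, sun_params):
    coarse = tk.run_trial(sun_pop, protocol(horizon_weeks=30), sun_params,
                          seed=6, step_h=4.0)
    fine = tk.run_trial(sun_pop, protocol(horizon_weeks=30), sun_params,
                        seed=6, step_h=2.0)
    both = np.isfinite(coarse.death_time_h) & np.isfinite(fine.death_time_h)
    if both.any():
        assert np.median(np.abs(coarse.death_time_h[both]
                                - fine.death_time_h[both])) < 48.0
    flips = np.mean((coarse.death_time_h > 30 * 168)
                    != (fine.death_time_h > 30 * 168))
    assert flips <= 0.05


# ---------------------------------------------------------------------------
# summaries and scans
# ---------------------------------------------------------------------------

def test_summary_all_alive_is_hundred_percent(sun_pop, inert_sun_params):
    ps = tk.ParameterSet.from_dict(inert_sun_params.to_dict())
    ps.fixed_effects["os_tad_weib_scale_h"] = 1e9
    ps.fixed_effects["os_bad_weib_scale_h"] = 1e9
    res = tk.run_trial(sun_pop, protocol(), ps, seed=3)
    s = tk.summarize_outcomes(res, 12)
    assert s["survival_pct"] == 100.0
    assert s["neutropenia_max_pct"] == 0.0   # inert drug: AE never occurs
    assert s["cumulative_ae_count"] == 0


def test_summary_rejects_empty_and_unknown_metric(sun_pop, sun_params):
    res = tk.run_trial(sun_pop, protocol(), sun_params, seed=3)
    with pytest.raises(ValueError):
        tk.summarize_outcomes(res, 12, ae_metric="bogus")


def test_cutoff_grids_cover_stated_ranges():
    assert tk.CUTOFF_GRIDS["TDM"][0] == 0.0 and tk.CUTOFF_GRIDS["TDM"][-1] == 80.0
    assert tk.CUTOFF_GRIDS["BAD_sVEGFR3"][0] == 0.0
    assert max(tk.CUTOFF_GRIDS["BAD_sVEGFR3"]) == pytest.approx(0.80)
    assert max(tk.CUTOFF_GRIDS["TAD_dBP"]) == pytest.approx(0.40)
    assert max(tk.CUTOFF_GRIDS["TAD_ANC"]) == pytest.approx(0.80)


def test_degenerate_cutoff_reproduces_fixed_arm_exactly(sun_pop, sun_params):
    """A cutoff that never triggers adjustment equals the fixed-dose arm
    bit-for-bit under common random numbers."""
    fixed = tk.run_trial(sun_pop, protocol(horizon_weeks=24, os_model="TAD"),
                         sun_params, seed=5)
    degen = tk.run_trial(
        sun_pop, protocol(horizon_weeks=24, adaptation="TDM", threshold=0.0,
                          os_model="TAD"), sun_params, seed=5)
    assert np.array_equal(fixed.death_time_h, degen.death_time_h)
    assert np.array_equal(fixed.dose_given, degen.dose_given)
    for k in fixed.series:
        assert np.array_equal(fixed.series[k], degen.series[k])


def test_scan_thresholds_table_shape(sun_pop, sun_params):
    df = tk.scan_thresholds(sun_pop, protocol(adaptation="TDM", threshold=0.0),
                            sun_params, cutoffs=[0.0, 50.0], seed=5,
                            t_weeks=12)
    assert list(df["cutoff"]) == [0.0, 50.0]
    assert "survival_pct" in df.columns
    with pytest.raises(ValueError):
        tk.scan_thresholds(sun_pop, protocol(adaptation="TDM", threshold=0.0),
                           sun_params, cutoffs=[], seed=5)


def test_event_table_export(sun_pop, sun_params):
    res = tk.run_trial(sun_pop, protocol(), sun_params, seed=3)
    df = res.event_table(12)
    assert {"id", "death_time_h", "dropout_time_h", "alive_at_12w"} <= set(df.columns)
    assert len(df) == len(sun_pop)


def test_long_format_export(sun_pop, sun_params):
    res = tk.run_trial(sun_pop, protocol(), sun_params, seed=3)
    df = res.long_frame(patients=[0, 1])
    assert set(df.columns) == {"id", "time_h", "name", "value"}
    assert set(df["id"]) == {0, 1}
    assert "svegfr3" in set(df["name"]) and "grade_hfs" in set(df["name"])
    days = res.days.size
    series_count = len(res.series) + len(res.true_grades)
    assert len(df) == 2 * days * series_count
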