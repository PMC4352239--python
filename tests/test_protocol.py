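"""Protocol engine: RM, titration, closed-loop controllers."""

import numpy as np
import pytest

from ventsi import (
    ProtocolParams,
    TitrationError,
    VentSettings,
    decremental_peep_titration,
    default_study_patient,
    make_patient,
    recruitment_maneuver,
    run_experiment,
    run_protocol,
)
from ventsi.protocol import ProtocolState, ph_rescue, rr_review, vt_controller_step


@pytest.fixture(scope="module")
def si_run():
    patient = default_study_patient(seed=1)
    return run_protocol(patient, "si_target", seed=1)


@pytest.fixture(scope="module")
def pplat_run():
    patient = default_study_patient(seed=1)
    return run_protocol(patient, "pplat_target", seed=1)


def _state(arm="pplat_target", rr=22.0, vt=8.0):
    settings = VentSettings(mode="VCV", vt_ml_per_kg=vt, rr=rr, peep=18.0)
    return ProtocolState(arm=arm, settings=settings, ol_peep=18.0)


# ----------------------------------------------------------------- RM
def test_rm_staircase_reaches_50_cmh2o(injured_patient):
    _, log = recruitment_maneuver(injured_patient)
    peeps = [stage["peep"] for stage in log]
    assert peeps == [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
    assert log[-1]["peak_paw"] == pytest.approx(50.0, abs=1.0)
    assert log[-1]["n_breaths"] == 20
    assert injured_patient.open_fraction > 0.99


# ----------------------------------------------------------- titration
def test_titration_ol_peep_is_best_crs_plus_two(injured_patient):
    recruitment_maneuver(injured_patient)
    result = decremental_peep_titration(injured_patient)
    best = result.peep_steps[int(np.argmax(result.crs_at_step))]
    assert result.best_crs_peep == best
    assert result.ol_peep == best + 2.0


def test_titration_stops_two_steps_past_maximum(injured_patient):
    recruitment_maneuver(injured_patient)
    result = decremental_peep_titration(injured_patient)
    best_idx = int(np.argmax(result.crs_at_step))
    assert len(result.crs_at_step) - 1 - best_idx == 2


def test_titration_without_interior_maximum_raises():
    healthy = make_patient(seed=1)
    recruitment_maneuver(healthy)
    with pytest.raises(TitrationError):
        decremental_peep_titration(healthy)


# --------------------------------------------------------- controllers
def test_ph_rescue_increments_rr_by_one():
    state = _state(rr=30.0)
    ph_rescue(state, {"ph": 7.10})
    assert state.settings.rr == 31.0


def test_ph_rescue_respects_cap():
    state = _state(rr=35.0)
    ph_rescue(state, {"ph": 7.05})
    assert state.settings.rr == 35.0
    assert not any(h["action"] == "rr_rescue_increase" for h in state.history)


def test_ph_rescue_inactive_above_threshold():
    state = _state(rr=30.0)
    ph_rescue(state, {"ph": 7.151})
    assert state.settings.rr == 30.0


def test_vt_steps_are_one_ml_per_kg():
    state = _state(arm="pplat_target", vt=8.0)
    vt_controller_step(state, {"pplat": 33.0, "ph": 7.30})
    assert state.settings.vt_ml_per_kg == 7.0
    state = _state(arm="si_target", vt=6.0)
    vt_controller_step(state, {"si": 0.80, "ph": 7.30})
    assert state.settings.vt_ml_per_kg == 7.0


def test_vt_floor():
    state = _state(arm="si_target", vt=3.0)
    vt_controller_step(state, {"si": 1.30, "ph": 7.30})
    assert state.settings.vt_ml_per_kg == 3.0


def test_rescue_vt_increase_overrides_arm_rule():
    """pH at the cap wins over a decrease the arm rule would command."""
    state = _state(arm="pplat_target", rr=35.0, vt=6.0)
    vt_controller_step(state, {"pplat": 33.0, "ph": 7.05})
    assert state.settings.vt_ml_per_kg == 7.0
    assert any(h["action"] == "vt_rescue_increase" for h in state.history)


def test_si_band_holds_vt():
    state = _state(arm="si_target", vt=6.0)
    vt_controller_step(state, {"si": 1.00, "ph": 7.30})
    assert state.settings.vt_ml_per_kg == 6.0


def test_rr_review_is_clamped():
    state = _state(rr=30.0)
    rr_review(state, {"paco2": 120.0})
    assert state.settings.rr == 35.0
    state = _state(rr=10.0)
    rr_review(state, {"paco2": 5.0})
    assert state.settings.rr == 6.0


def test_rr_review_inactive_inside_band():
    state = _state(rr=22.0)
    rr_review(state, {"paco2": 50.0})
    assert state.settings.rr == 22.0


# ------------------------------------------------------- closed loop
def test_snapshots_hourly_through_four_hours(si_run):
    _, trace = si_run
    assert list(trace.snapshots["T"]) == ["T0", "T1", "T2", "T3", "T4"]
    assert list(trace.snapshots["t_min"]) == [0.0, 60.0, 120.0, 180.0, 240.0]


def test_all_logged_vt_changes_are_single_steps(si_run, pplat_run):
    for _, trace in (si_run, pplat_run):
        vt_series = trace.actions.loc[
            trace.actions["action"].str.startswith("vt"), "vt_ml_per_kg"
        ].dropna().to_numpy()
        assert np.all(np.abs(np.diff(vt_series)) <= 1.0 + 1e-12)


def test_rr_never_exceeds_cap(si_run, pplat_run):
    for _, trace in (si_run, pplat_run):
        rr_values = trace.actions["rr"].dropna()
        if len(rr_values):
            assert rr_values.max() <= 35.0


def test_si_arm_settles_inside_band(si_run):
    _, trace = si_run
    final = trace.snapshots.iloc[-1]
    assert 0.95 <= final["si"] <= 1.05


def test_paired_arm_comparison(si_run, pplat_run):
    """SI guidance sustains a larger VT and lower PaCO2 than Pplat guidance."""
    _, si_trace = si_run
    _, pp_trace = pplat_run
    si_final = si_trace.snapshots.iloc[-1]
    pp_final = pp_trace.snapshots.iloc[-1]
    assert si_final["vt_ml_kg"] > pp_final["vt_ml_kg"]
    assert si_final["paco2"] < pp_final["paco2"]


def test_runs_are_deterministic():
    t1 = run_protocol(default_study_patient(seed=1), "si_target", duration_min=20.0, seed=1)
    t2 = run_protocol(default_study_patient(seed=1), "si_target", duration_min=20.0, seed=1)
    assert t1[1].snapshots.equals(t2[1].snapshots)
    assert t1[1].actions.equals(t2[1].actions)


def test_custom_params_change_behaviour():
    patient = default_study_patient(seed=1)
    recruitment_maneuver(patient)
    tit = decremental_peep_titration(patient)
    params = ProtocolParams(rr_cap=20.0)
    start = VentSettings(mode="VCV", vt_ml_per_kg=8.0, rr=15.0, peep=tit.ol_peep)
    trace = run_experiment(patient, "pplat_target", tit.ol_peep,
                           duration_min=120.0, seed=1, params=params,
                           initial_settings=start)
    rescues = trace.actions[trace.actions["action"] == "rr_rescue_increase"]
    assert len(rescues) > 0
    assert rescues["rr"].max() <= 20.0
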