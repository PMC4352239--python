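"""Protocol engine: recruitment, PEEP titration and closed-loop VT control.

The study protocol consists of:

1. A staircase recruitment manoeuvre (RM) in pressure-controlled
   ventilation (driving pressure 20 cmH2O, RR 10), PEEP 5 -> 30 in
   5-cmH2O steps of 10 breaths each, with the final opening pressure of
   50 cmH2O held for 20 breaths (two minutes).
2. A decremental PEEP trial (VCV, 6 ml/kg, RR 20) from PEEP 30 in
   2-cmH2O steps of two minutes each until the best respiratory-system
   compliance is detected; the open-lung PEEP (OL-PEEP) is the
   best-compliance PEEP plus 2 cmH2O, applied after a second RM.
3. Four hours of closed-loop ventilation at OL-PEEP in one of two arms:
   VT titrated in 1-ml/kg steps every five minutes to a plateau
   pressure of 30 cmH2O (``pplat_target``) or to a stress index inside
   [0.95, 1.05] (``si_target``).  A pH-rescue ladder runs throughout:
   when pH <= 7.15 and RR < 35 bpm, RR rises 1 bpm per minute; when
   pH <= 7.15 at the RR cap of 35, VT rises 1 ml/kg regardless of the
   arm's target.  An hourly blood-gas review retargets RR to keep
   PaCO2 within 35-65 mmHg.  Full measurement snapshots are logged at
   T0 (start) and every 60 minutes up to T4 (240 min).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import gas as gasmod
from .errors import TitrationError
from .patient import BreathRecord, VentSettings, VirtualPatient, run_ventilation, simulate_breath
from .waveform import compute_mechanics, fit_stress_index

Arm = Literal["pplat_target", "si_target"]
Phase = Literal["baseline", "injury_stabilization", "rm", "titration", "rm2", "experiment"]

SNAPSHOT_TIMES_MIN = (0.0, 60.0, 120.0, 180.0, 240.0)


@dataclass(frozen=True)
class ProtocolParams:
    """Controller targets, thresholds and cadences (defaults as printed)."""

    pplat_target: float = 30.0      # cmH2O
    pplat_dec_tol: float = 0.5      # decrease VT when pplat > target + tol
    pplat_inc_below: float = 29.0   # increase VT only when pplat <= this
    si_low: float = 0.95
    si_high: float = 1.05
    ph_rescue: float = 7.15
    rr_cap: float = 35.0            # bpm
    rr_floor: float = 6.0
    paco2_low: float = 35.0         # mmHg
    paco2_high: float = 65.0
    paco2_review_target: float = 55.0
    vt_floor: float = 3.0           # ml/kg
    vt_step: float = 1.0
    vt_review_s: float = 300.0
    rr_rescue_review_s: float = 60.0
    rr_review_s: float = 3600.0


@dataclass
class ProtocolState:
    """Mutable controller state during the experiment phase."""

    arm: Arm
    settings: VentSettings
    ol_peep: float
    params: ProtocolParams = field(default_factory=ProtocolParams)
    elapsed: float = 0.0
    next_vt_review: float = 300.0
    next_rr_review: float = 3600.0
    phase: Phase = "experiment"
    history: list[dict] = field(default_factory=list)
    vt_too_high: float | None = None  # anti-oscillation guard (ml/kg)

    def log(self, action: str, **detail) -> None:
        self.history.append({"time_s": self.elapsed, "action": action, **detail})


@dataclass(frozen=True)
class TitrationResult:
    """Outcome of the decremental PEEP trial."""

    peep_steps: list[float]
    crs_at_step: list[float]
    best_crs_peep: float
    ol_peep: float


@dataclass
class ExperimentTrace:
    """Snapshots (T0-T4) and controller actions of one closed-loop run."""

    arm: Arm
    ol_peep: float
    snapshots: pd.DataFrame
    actions: pd.DataFrame


# ----------------------------------------------------------------------
# recruitment manoeuvre and PEEP titration
# ----------------------------------------------------------------------
RM_DRIVING_PRESSURE = 20.0
RM_RR = 10.0
RM_PEEP_STEPS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
RM_BREATHS_PER_STEP = 10
RM_FINAL_BREATHS = 20


def recruitment_maneuver(
    patient: VirtualPatient, sample_rate: float = 100.0
) -> tuple[VirtualPatient, list[dict]]:
    """Staircase RM in PCV; mutates and returns the patient plus a stage log.

    PEEP rises 5 -> 30 cmH2O in 5-cmH2O steps of 10 breaths at RR 10
    with a driving pressure of 20 cmH2O; the final stage (opening
    pressure 50 cmH2O) lasts 20 breaths, i.e. two minutes.
    """
    log: list[dict] = []
    for peep in RM_PEEP_STEPS:
        n = RM_FINAL_BREATHS if peep == RM_PEEP_STEPS[-1] else RM_BREATHS_PER_STEP
        settings = VentSettings(
            mode="PCV", rr=RM_RR, peep=peep,
            driving_pressure=RM_DRIVING_PRESSURE, pause_fraction=0.0,
            vt_ml_per_kg=8.0,  # unused in PCV
        )
        peak = 0.0
        for _ in range(n):
            breath = simulate_breath(patient, settings, sample_rate)
            peak = max(peak, float(np.max(breath.paw)))
        log.append({
            "peep": peep, "n_breaths": n, "peak_paw": peak,
            "duration_s": n * settings.period,
            "open_fraction": patient.open_fraction,
        })
    return patient, log


TITRATION_VT = 6.0
TITRATION_RR = 20.0
TITRATION_START_PEEP = 30.0
TITRATION_STEP = 2.0
TITRATION_STEP_S = 120.0
TITRATION_FLOOR = 4.0
TITRATION_PATIENCE = 2  # stop this many steps after the running maximum


def decremental_peep_titration(
    patient: VirtualPatient, sample_rate: float = 100.0
) -> TitrationResult:
    """Decremental PEEP trial; returns the OL-PEEP and applies it.

    Runs VCV at 6 ml/kg, RR 20 from PEEP 30 downward in 2-cmH2O steps of
    two minutes; the per-step Crs is the mean over the step's final five
    breaths.  The trial stops two steps after the running Crs maximum
    stops improving (ties resolve to the higher PEEP); OL-PEEP is the
    best-Crs PEEP + 2 cmH2O, applied after a second recruitment
    manoeuvre.  Raises :class:`TitrationError` when Crs is still
    improving at the PEEP floor of 4 cmH2O.
    """
    peep_steps: list[float] = []
    crs_steps: list[float] = []
    best_idx = -1
    best_crs = -np.inf
    peep = TITRATION_START_PEEP
    while peep >= TITRATION_FLOOR - 1e-9:
        settings = VentSettings(
            mode="VCV", vt_ml_per_kg=TITRATION_VT, rr=TITRATION_RR, peep=peep
        )
        breaths = run_ventilation(patient, settings, TITRATION_STEP_S, sample_rate)
        crs = float(np.mean(
            [compute_mechanics(b, b.vt_ml).crs for b in breaths[-5:]]
        ))
        peep_steps.append(peep)
        crs_steps.append(crs)
        if crs > best_crs:  # strict: ties keep the earlier (higher) PEEP
            best_crs, best_idx = crs, len(crs_steps) - 1
        elif len(crs_steps) - 1 - best_idx >= TITRATION_PATIENCE:
            break
        peep -= TITRATION_STEP
    else:
        raise TitrationError(
            "compliance still improving at the PEEP floor "
            f"({TITRATION_FLOOR} cmH2O); no interior maximum detected"
        )
    best_peep = peep_steps[best_idx]
    ol_peep = best_peep + 2.0
    recruitment_maneuver(patient, sample_rate)
    patient.settle(ol_peep)
    return TitrationResult(
        peep_steps=peep_steps, crs_at_step=crs_steps,
        best_crs_peep=best_peep, ol_peep=ol_peep,
    )


# ----------------------------------------------------------------------
# closed-loop controllers
# ----------------------------------------------------------------------
def ph_rescue(state: ProtocolState, meas: dict) -> ProtocolState:
    """Minute-cadence rescue: pH <= 7.15 and RR < 35 -> RR + 1 bpm."""
    p = state.params
    ph = meas.get("ph")
    if ph is None:
        state.log("rr_rescue_skipped", reason="missing ph")
        return state
    if ph <= p.ph_rescue and state.settings.rr < p.rr_cap:
        new_rr = min(state.settings.rr + 1.0, p.rr_cap)
        state.settings = replace(state.settings, rr=new_rr)
        state.log("rr_rescue_increase", rr=new_rr, ph=ph)
    return state


def vt_controller_step(state: ProtocolState, meas: dict) -> ProtocolState:
    """Five-minute VT review: arm target rule, then the rescue override.

    Pplat arm: VT falls 1 ml/kg when Pplat exceeds 30 cmH2O (beyond a
    0.5-cmH2O quantization deadband) and rises 1 ml/kg when Pplat <= 29,
    unless that VT already proved too high (anti-oscillation guard).
    SI arm: VT falls when SI > 1.05 and rises when SI < 0.95.  When
    pH <= 7.15 at the 35-bpm RR cap, VT rises 1 ml/kg irrespective of
    the target.  VT never falls below 3 ml/kg.
    """
    p = state.params
    vt = state.settings.vt_ml_per_kg
    delta = 0.0
    if state.arm == "pplat_target":
        pplat = meas.get("pplat")
        if pplat is None:
            state.log("vt_review_skipped", reason="missing pplat")
            return state
        if pplat > p.pplat_target + p.pplat_dec_tol:
            delta = -p.vt_step
            state.vt_too_high = vt
        elif pplat <= p.pplat_inc_below and vt + p.vt_step != state.vt_too_high:
            delta = p.vt_step
    else:
        si = meas.get("si")
        if si is None:
            state.log("vt_review_skipped", reason="missing si")
            return state
        if si > p.si_high:
            delta = -p.vt_step
        elif si < p.si_low:
            delta = p.vt_step

    ph = meas.get("ph")
    rescue = ph is not None and ph <= p.ph_rescue and state.settings.rr >= p.rr_cap
    if rescue:
        delta = p.vt_step  # overrides the arm's rule

    new_vt = max(vt + delta, p.vt_floor)
    if new_vt != vt:
        state.settings = replace(state.settings, vt_ml_per_kg=new_vt)
        state.log(
            "vt_rescue_increase" if rescue else "vt_adjust",
            vt_ml_per_kg=new_vt, delta=new_vt - vt, **{
                k: meas[k] for k in ("pplat", "si", "ph") if meas.get(k) is not None
            },
        )
    else:
        state.log("vt_hold", vt_ml_per_kg=vt)
    return state


def rr_review(state: ProtocolState, meas: dict) -> ProtocolState:
    """Hourly blood-gas review: retarget RR when PaCO2 leaves 35-65 mmHg.

    RR is rescaled in proportion to the PaCO2 excess relative to a
    55-mmHg target (the band midpoint area), clamped to [6, 35] bpm.
    """
    p = state.params
    paco2 = meas.get("paco2")
    if paco2 is None:
        state.log("rr_review_skipped", reason="missing paco2")
        return state
    if not p.paco2_low <= paco2 <= p.paco2_high:
        new_rr = float(np.clip(
            round(state.settings.rr * paco2 / p.paco2_review_target),
            p.rr_floor, p.rr_cap,
        ))
        if new_rr != state.settings.rr:
            state.settings = replace(state.settings, rr=new_rr)
            state.log("rr_review_adjust", rr=new_rr, paco2=paco2)
    return state


# ----------------------------------------------------------------------
# the timed experiment
# ----------------------------------------------------------------------
def _measure(
    patient: VirtualPatient,
    settings: VentSettings,
    gas_state: gasmod.GasState,
    sample_rate: float,
    breaths: int,
    rng: np.random.Generator,
) -> tuple[dict, list[BreathRecord]]:
    """Simulate a few representative breaths and assemble a measurement set.

    The reported SI is the median over the simulated breaths of the
    30-s reporting interval.
    """
    records = [simulate_breath(patient, settings, sample_rate, rng) for _ in range(breaths)]
    b_values = [fit_stress_index(r).b for r in records]
    last = records[-1]
    mech = compute_mechanics(last, last.vt_ml)
    meas = {
        "si": statistics.median(b_values),
        "pplat": mech.pplat,
        "total_peep": mech.total_peep,
        "crs": mech.crs, "cl": mech.cl, "ccw": mech.ccw,
        "ptp_ee": mech.ptp_ee, "ptp_ei": mech.ptp_ei, "dptp": mech.dptp,
        "auto_peep": mech.auto_peep,
        "ph": gas_state.ph, "paco2": gas_state.paco2,
        "pf_ratio": patient.pf_ratio(),
        "vt_ml": last.vt_ml,
    }
    return meas, records


def run_experiment(
    patient: VirtualPatient,
    arm: Arm,
    ol_peep: float,
    duration_min: float = 240.0,
    initial_settings: VentSettings | None = None,
    gas_state: gasmod.GasState | None = None,
    sample_rate: float = 100.0,
    tick_s: float = 30.0,
    breaths_per_tick: int = 3,
    seed: int = 0,
    params: ProtocolParams | None = None,
) -> ExperimentTrace:
    """Closed-loop ventilation at OL-PEEP under the assigned arm.

    Advances in 30-s ticks (the SI reporting cadence): each tick
    simulates representative breaths, fits the stress index, reads the
    occlusion mechanics, then runs the controllers at their cadences
    (rescue every minute, VT review every 5 minutes, blood-gas RR review
    hourly) and advances the CO2 store analytically.  Measurement
    snapshots are logged at T0 and every 60 min through T4.
    """
    if initial_settings is None:
        initial_settings = VentSettings(
            mode="VCV", vt_ml_per_kg=8.0, rr=22.0, peep=ol_peep
        )
    settings = replace(initial_settings, peep=ol_peep)
    if params is None:
        params = ProtocolParams()
    state = ProtocolState(arm=arm, settings=settings, ol_peep=ol_peep, params=params)
    rng = np.random.default_rng(seed)
    if gas_state is None:
        gas_state = gasmod.initial_gas_state(patient, settings)

    snapshot_s = [m * 60.0 for m in SNAPSHOT_TIMES_MIN if m <= duration_min]
    snapshots: list[dict] = []
    n_ticks = int(round(duration_min * 60.0 / tick_s))

    for tick in range(n_ticks + 1):
        t = tick * tick_s
        state.elapsed = t
        meas, _ = _measure(
            patient, state.settings, gas_state, sample_rate, breaths_per_tick, rng
        )

        if any(abs(t - s) < tick_s / 2 for s in snapshot_s):
            label = f"T{snapshot_s.index(min(snapshot_s, key=lambda s: abs(s - t)))}"
            snapshots.append({
                "T": label, "t_min": t / 60.0,
                "vt_ml_kg": state.settings.vt_ml_per_kg,
                "rr": state.settings.rr,
                "ve": state.settings.rr * meas["vt_ml"] / 1000.0,
                "si": meas["si"], "pplat": meas["pplat"],
                "ptp_ee": meas["ptp_ee"], "ptp_ei": meas["ptp_ei"],
                "dptp": meas["dptp"], "crs": meas["crs"],
                "ccw": meas["ccw"], "cl": meas["cl"],
                "ph": meas["ph"], "paco2": meas["paco2"],
                "pf_ratio": meas["pf_ratio"],
            })
        if tick == n_ticks:
            break

        # controllers at their cadences (after the measurement at time t)
        if t > 0 and t % params.rr_rescue_review_s < tick_s / 2:
            ph_rescue(state, meas)
        if t > 0 and t % params.rr_review_s < tick_s / 2:
            rr_review(state, meas)
        if t > 0 and t % params.vt_review_s < tick_s / 2:
            vt_controller_step(state, meas)

        va = gasmod.alveolar_ventilation(state.settings, patient)
        gas_state = gasmod.co2_step(patient, gas_state, va, tick_s)

    return ExperimentTrace(
        arm=arm, ol_peep=ol_peep,
        snapshots=pd.DataFrame(snapshots),
        actions=pd.DataFrame(state.history, columns=None),
    )


def run_protocol(
    patient: VirtualPatient,
    arm: Arm,
    duration_min: float = 240.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    params: ProtocolParams | None = None,
    initial_settings: VentSettings | None = None,
) -> tuple[TitrationResult, ExperimentTrace]:
    """Full protocol on an injured patient: RM, titration, second RM, arm run."""
    recruitment_maneuver(patient, sample_rate)
    titration = decremental_peep_titration(patient, sample_rate)
    trace = run_experiment(
        patient, arm, titration.ol_peep,
        duration_min=duration_min, sample_rate=sample_rate, seed=seed,
        params=params, initial_settings=initial_settings,
    )
    return titration, trace
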