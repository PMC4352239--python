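"""Pressure-time waveform analysis.

During constant inspiratory flow, volume rises linearly with time, so
the shape of the inspiratory pressure-time curve reflects the dynamic
compliance of the respiratory system across the tidal breath.  The
curve is summarised by the power-law fit

    P(t) = a * t**b + c

where ``b`` is the stress index (SI): ``b`` near 1 means a straight
line (constant compliance, non-injurious ventilation), ``b > 1.05`` an
upward concavity (falling compliance, tidal overdistension) and
``b < 0.95`` a downward concavity (rising compliance, tidal
recruitment).  ``a`` is the slope scale and ``c`` the pressure at the
start of the fitted window.

The module also computes static mechanics from the occlusion pressures
(respiratory-system, lung and chest-wall compliance, transpulmonary
pressures) and detects auto-PEEP from the expiratory flow trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConstantFlowError, FitError, TruncatedTraceError, UndefinedComplianceError
from .patient import BreathRecord

SI_THRESHOLDS = (0.95, 1.05)
_B_BOUNDS = (0.3, 3.0)

Label = Literal["tidal_recruitment", "non_injurious", "overdistension"]


@dataclass(frozen=True)
class StressIndexFit:
    """Power-law fit of the inspiratory pressure-time curve."""

    a: float
    b: float
    c: float
    rss: float
    n_points: int
    window: tuple[float, float]
    label: Label


@dataclass(frozen=True)
class RespiratoryMechanics:
    """Static mechanics derived from the occlusion pressures of one breath.

    Compliances in ml/cmH2O, pressures in cmH2O.
    """

    crs: float
    cl: float
    ccw: float
    ptp_ee: float
    ptp_ei: float
    dptp: float
    pplat: float
    total_peep: float
    auto_peep: bool


def classify_si(b: float, thresholds: tuple[float, float] = SI_THRESHOLDS) -> Label:
    """Classify a stress index; the band is closed: t_low <= b <= t_high."""
    t_low, t_high = thresholds
    if b < t_low:
        return "tidal_recruitment"
    if b > t_high:
        return "overdistension"
    return "non_injurious"


def extract_constant_flow_window(
    breath: BreathRecord,
    rel_tol: float = 0.02,
    skip_fraction: float = 0.05,
    min_samples: int = 10,
) -> tuple[float, float]:
    """Locate the constant-flow portion of a VCV inspiration.

    Returns the [t_start, t_end] of the maximal contiguous span where
    flow is within ``rel_tol`` of the median inspiratory flow, after
    excluding the first ``skip_fraction`` of the inspiratory (pre-pause)
    time.  Raises :class:`ConstantFlowError` when no span of at least
    ``min_samples`` exists, e.g. for a decelerating-flow PCV breath.
    """
    flow = np.asarray(breath.flow)
    pos = flow > 1e-9
    if not pos[0] and pos.any():
        first = int(np.argmax(pos))
    elif pos.any():
        first = 0
    else:
        raise ConstantFlowError("no inspiratory flow in breath")
    # pre-pause inspiration: up to the first non-positive sample
    after = np.nonzero(~pos[first:])[0]
    end = first + (int(after[0]) if len(after) else len(flow) - first)
    insp = np.arange(first, end)
    if len(insp) < min_samples:
        raise ConstantFlowError("inspiratory flow phase too short")
    q_med = float(np.median(flow[insp]))
    ok = np.abs(flow[insp] - q_med) < rel_tol * q_med
    t_insp_flow = breath.t[insp[-1]] - breath.t[insp[0]]
    ok &= breath.t[insp] >= breath.t[insp[0]] + skip_fraction * t_insp_flow

    # maximal contiguous run of True
    best_len, best_start, run_len = 0, -1, 0
    for i, good in enumerate(ok):
        run_len = run_len + 1 if good else 0
        if run_len > best_len:
            best_len, best_start = run_len, i - run_len + 1
    if best_len < min_samples:
        raise ConstantFlowError(
            f"no constant-flow portion of >= {min_samples} samples "
            f"(longest run: {best_len})"
        )
    i0, i1 = insp[best_start], insp[best_start + best_len - 1]
    return float(breath.t[i0]), float(breath.t[i1])


def _power(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.power(t, b) + c


def fit_stress_index(
    breath: BreathRecord,
    signal: Literal["transpulmonary", "airway"] = "transpulmonary",
    thresholds: tuple[float, float] = SI_THRESHOLDS,
) -> StressIndexFit:
    """Fit P = a*t^b + c over the constant-flow window and classify.

    ``signal`` selects the fitted pressure: transpulmonary (airway minus
    pleural, matching the defining equation) or raw airway pressure.
    Time is re-zeroed at the window start.  ``b`` is constrained to
    [0.3, 3.0]; the fit restarts from perturbed initial guesses on
    failure.
    """
    t0, t1 = extract_constant_flow_window(breath)
    mask = (breath.t >= t0) & (breath.t <= t1)
    t = np.asarray(breath.t[mask], dtype=float) - t0
    if signal == "transpulmonary":
        p = np.asarray(breath.paw[mask] - breath.ppl[mask], dtype=float)
    elif signal == "airway":
        p = np.asarray(breath.paw[mask], dtype=float)
    else:
        raise ValueError(f"unknown signal {signal!r}")
    if not np.all(np.isfinite(p)):
        raise FitError("non-finite pressure samples in fit window")

    dt_span = t[-1] if t[-1] > 0 else 1.0
    a0 = max((p[-1] - p[0]) / dt_span, 1e-6)
    guesses = [(a0, 1.0, p[0]), (a0, 0.7, p[0]), (a0, 1.4, p[0]), (2 * a0, 1.0, p[0])]
    bounds = ([1e-9, _B_BOUNDS[0], -np.inf], [np.inf, _B_BOUNDS[1], np.inf])
    last_err: Exception | None = None
    for p0 in guesses:
        try:
            popt, _ = curve_fit(_power, t, p, p0=p0, bounds=bounds, maxfev=20000)
            resid = p - _power(t, *popt)
            rss = float(resid @ resid)
            a, b, c = (float(x) for x in popt)
            return StressIndexFit(
                a=a, b=b, c=c, rss=rss, n_points=len(t),
                window=(t0, t1), label=classify_si(b, thresholds),
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(
        f"stress-index fit failed to converge on window [{t0:.3f}, {t1:.3f}] s "
        f"({len(t)} samples, pressure range {p.min():.2f}-{p.max():.2f} cmH2O): {last_err}"
    )


def compute_mechanics(breath: BreathRecord, vt_ml: float) -> RespiratoryMechanics:
    """Static compliances and transpulmonary pressures from one breath.

    crs = VT / (Pplat - total PEEP); cl = VT / (P_TP,EI - P_TP,EE);
    ccw = VT / (Ppl,EI - Ppl,EE); P_TP = occlusion airway pressure minus
    the simultaneous pleural pressure.
    """
    if vt_ml <= 0:
        raise UndefinedComplianceError("vt_ml must be > 0")
    ptp_ei = breath.pplat - breath.ppl_ei
    ptp_ee = breath.total_peep - breath.ppl_ee
    d_rs = breath.pplat - breath.total_peep
    d_l = ptp_ei - ptp_ee
    d_cw = breath.ppl_ei - breath.ppl_ee
    for name, denom in (("crs", d_rs), ("cl", d_l), ("ccw", d_cw)):
        if denom <= 0:
            raise UndefinedComplianceError(
                f"undefined compliance: {name} denominator is {denom:.3f} cmH2O"
            )
    return RespiratoryMechanics(
        crs=vt_ml / d_rs,
        cl=vt_ml / d_l,
        ccw=vt_ml / d_cw,
        ptp_ee=ptp_ee,
        ptp_ei=ptp_ei,
        dptp=ptp_ei - ptp_ee,
        pplat=breath.pplat,
        total_peep=breath.total_peep,
        auto_peep=detect_auto_peep(breath),
    )


def detect_auto_peep(breath: BreathRecord, zero_flow_tol: float = 0.01) -> bool:
    """True when expiratory flow has not reached zero at the next-breath onset.

    Inspects the final sample of the record (the instant the next
    inspiration would begin).  Raises :class:`TruncatedTraceError` when
    the record contains no expiratory phase.
    """
    flow = np.asarray(breath.flow)
    if not (flow < -1e-12).any():
        raise TruncatedTraceError("breath record contains no expiratory flow")
    return bool(abs(float(flow[-1])) > zero_flow_tol)


def breath_metrics_row(
    breath_id: int, breath: BreathRecord, vt_ml: float | None = None,
    signal: Literal["transpulmonary", "airway"] = "transpulmonary",
) -> dict:
    """One row of the per-breath metrics table (CSV-friendly)."""
    vt = breath.vt_ml if vt_ml is None else vt_ml
    fit = fit_stress_index(breath, signal=signal)
    mech = compute_mechanics(breath, vt)
    return {
        "breath_id": breath_id,
        "si_b": fit.b, "si_a": fit.a, "si_c": fit.c, "label": fit.label,
        "crs": mech.crs, "cl": mech.cl, "ccw": mech.ccw,
        "ptp_ee": mech.ptp_ee, "ptp_ei": mech.ptp_ei, "dptp": mech.dptp,
        "pplat": mech.pplat, "total_peep": mech.total_peep,
        "auto_peep": mech.auto_peep,
    }
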