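"""Virtual-patient lung simulator.

A ventilated subject is modelled as ``n_units`` parallel lung units with
hysteretic threshold recruitment, feeding a common compliant compartment
with a volume-dependent elastic recoil, in series with a linear chest
wall whose stiffness is coupled to intra-abdominal pressure (IAP).

Model summary
-------------
Let ``V`` be lung volume above the relaxation volume (L) and ``f`` the
fraction of units currently open.  Open units share the volume, so the
per-unit strain scales with the *equivalent* volume ``Veff = V / f``:

* lung recoil           ``P_L  = E1 * Veff + E2 * Veff**2``
* pleural pressure      ``Ppl  = ppl0 + Ecw_eff * V``
* alveolar pressure     ``Palv = P_L + Ppl``
* airway pressure       ``Paw  = Palv + Raw * flow``

with ``Ecw_eff = Ecw_base * (1 + k_iap * IAP)`` and
``ppl0 = ppl_base + k_ppl * IAP * MMHG_TO_CMH2O``.  A unit opens during
inspiration when alveolar pressure exceeds its opening threshold and
closes at end-expiration when alveolar pressure falls below its closing
threshold (closing < opening: hysteresis).  Gas held by a closing unit is
expelled, so ``Veff`` (and hence recoil) is continuous across closure.

Volume-controlled breaths deliver a square inspiratory flow with a
two-sample ramp at each transition; expiration is passive through the
airway resistance against the set PEEP.  Occlusion pressures are read
from simulated 3-second zero-flow holds (mean of the final 0.2 s).

Surfactant-depletion-type injury raises the unit opening thresholds and
the lung elastances; intra-abdominal hypertension stiffens the chest
wall and shifts the pleural baseline.  Default parameters are calibrated
once so that full injury plus IAP 26 mmHg reduces chest-wall compliance
by about 57% and lung compliance by about 62% under baseline ventilation,
and are then frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ConfigurationError, TimingError

MMHG_TO_CMH2O = 1.36

#: Default per-unit threshold statistics (cmH2O).  Closing pressures are
#: narrowly distributed (full injury: mean 11, SD 2.5) so that an
#: open-lung PEEP a few cmH2O above them keeps the lung open, while the
#: opening pressures sit a broad hysteresis gap above (full injury:
#: +8 to +28 cmH2O, clipped at 45) so that reopening requires a
#: recruitment manoeuvre and spreads across the tidal pressure range.
_CLOSE_MEAN_HEALTHY = 1.0
_CLOSE_SD_HEALTHY = 0.5
_CLOSE_MEAN_INJURED = 10.0
_CLOSE_SD_INJURED = 4.0
_GAP_BASE_HEALTHY = 2.0
_GAP_BASE_INJURED = 8.0
_GAP_SPREAD_INJURED = 20.0
_CLOSE_FLOOR = 0.3
_OPEN_CLIP = (1.0, 45.0)

#: Elastance scaling with injury severity: E1 * (1 + severity * K_E1) etc.
_K_E1 = 1.0
_K_E2 = 4.0

#: PaO2/FiO2 mapping from the non-aerated unit fraction (monotone shunt
#: surrogate; used for injury-endpoint checks only).
_PF_HEALTHY = 515.0
_PF_EXPONENT = 1.7
_PF_FIXED_SHUNT = 0.5


@dataclass
class VentSettings:
    """Ventilator settings for one breath or a ventilation epoch.

    ``ie_ratio`` is the inspiratory:expiratory time ratio expressed as
    I/E (1:2 -> 0.5).  ``pause_fraction`` is the end-inspiratory pause as
    a fraction of inspiratory time.  ``driving_pressure`` only applies in
    PCV mode.
    """

    mode: Literal["VCV", "PCV"] = "VCV"
    vt_ml_per_kg: float = 8.0
    rr: float = 22.0
    peep: float = 5.0
    ie_ratio: float = 0.5
    pause_fraction: float = 0.10
    fio2: float = 1.0
    driving_pressure: float = 20.0

    def __post_init__(self) -> None:
        if self.vt_ml_per_kg <= 0:
            raise ConfigurationError("vt_ml_per_kg must be > 0")
        if not 0 <= self.pause_fraction <= 0.5:
            raise ConfigurationError("pause_fraction must be in [0, 0.5]")
        if self.rr <= 0:
            raise ConfigurationError("rr must be > 0")
        if self.ie_ratio <= 0:
            raise ConfigurationError("ie_ratio must be > 0")

    @property
    def period(self) -> float:
        """Breath period (s)."""
        return 60.0 / self.rr

    @property
    def t_insp(self) -> float:
        """Inspiratory time including the in-breath pause (s)."""
        return self.period * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp(self) -> float:
        """Expiratory time (s)."""
        return self.period - self.t_insp


@dataclass
class BreathRecord:
    """Sampled waveforms and occlusion readings for one breath."""

    t: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    ppl: np.ndarray
    volume: np.ndarray
    pplat: float
    total_peep: float
    ppl_ei: float
    ppl_ee: float
    sample_rate: float
    vt_ml: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.flow) == len(self.paw) == len(self.ppl) == len(self.volume) == n):
            raise ConfigurationError("breath arrays must have equal length")


@dataclass
class VirtualPatient:
    """State of the simulated ventilated subject.

    Mechanical parameters are for the *healthy* subject; the effective
    (injured) values are exposed as properties.  ``unit_state`` is True
    for open units.  ``v_ee`` carries the end-expiratory volume (L above
    relaxation volume) across breaths.
    """

    weight: float = 32.0
    n_units: int = 500
    E1: float = 21.5          # cmH2O/L
    E2: float = 2.0           # cmH2O/L^2
    Raw: float = 10.0         # cmH2O*s/L
    Ecw_base: float = 12.5    # cmH2O/L
    IAP: float = 0.0          # mmHg
    k_iap: float = 0.051      # per mmHg
    k_ppl: float = 0.25       # pleural offset = k_ppl * IAP (in cmH2O)
    ppl_base: float = 0.0     # cmH2O
    FRC_healthy: float = 900.0  # ml
    vco2: float = 200.0       # ml/min STPD
    vd_aw: float = 77.0       # ml
    hco3: float = 24.0        # mmol/L
    co2_capacity: float = 64.0  # ml STPD per mmHg
    v_od: float = 0.30        # upper-inflection equivalent volume (L)
    k_od: float = 450.0       # supra-inflection elastance at full injury (cmH2O/L^2)
    severity: float = 0.0
    noise_sigma: float = 0.0  # pressure sensor noise SD (cmH2O)
    rng_seed: int = 0

    unit_opening_pressure: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    unit_closing_pressure: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    unit_state: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    v_ee: float = 0.0
    _z: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _u: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("E1", "Raw", "Ecw_base", "weight"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.E2 < 0:
            raise ConfigurationError("E2 must be >= 0")
        if self.IAP < 0:
            raise ConfigurationError("IAP must be >= 0")
        if not 0 <= self.severity <= 1:
            raise ConfigurationError("severity must be in [0, 1]")
        if self.n_units < 2:
            raise ConfigurationError("n_units must be >= 2")
        if self._z is None:
            rng = np.random.default_rng(self.rng_seed)
            self._z = rng.standard_normal(self.n_units)
            self._u = rng.random(self.n_units)
        if self.unit_opening_pressure is None:
            self._set_thresholds()
        if self.unit_state is None:
            self.unit_state = np.ones(self.n_units, dtype=bool)
        bad = self.unit_closing_pressure >= self.unit_opening_pressure
        if bad.any():
            raise ConfigurationError("unit closing pressure must be < opening pressure")

    # ------------------------------------------------------------------
    # parameterisation
    # ------------------------------------------------------------------
    def _set_thresholds(self) -> None:
        s = self.severity
        cmean = _CLOSE_MEAN_HEALTHY + s * (_CLOSE_MEAN_INJURED - _CLOSE_MEAN_HEALTHY)
        csd = _CLOSE_SD_HEALTHY + s * (_CLOSE_SD_INJURED - _CLOSE_SD_HEALTHY)
        gap = _GAP_BASE_HEALTHY + s * (
            _GAP_BASE_INJURED - _GAP_BASE_HEALTHY + _GAP_SPREAD_INJURED * self._u
        )
        closing = np.maximum(cmean + csd * self._z, _CLOSE_FLOOR)
        opening = np.clip(closing + gap, *_OPEN_CLIP)
        self.unit_opening_pressure = opening
        self.unit_closing_pressure = np.minimum(closing, opening - 0.5)

    @property
    def e1_eff(self) -> float:
        """Effective first-order lung elastance (cmH2O/L)."""
        return self.E1 * (1.0 + self.severity * _K_E1)

    @property
    def e2_eff(self) -> float:
        """Effective volume-dependent elastance coefficient (cmH2O/L^2)."""
        return self.E2 * (1.0 + self.severity * _K_E2)

    @property
    def e_od_eff(self) -> float:
        """Supra-inflection elastance (cmH2O/L^2); zero in the healthy lung."""
        return self.severity * self.k_od

    @property
    def ecw_eff(self) -> float:
        """Effective chest-wall elastance (cmH2O/L), stiffened by IAP."""
        return self.Ecw_base * (1.0 + self.k_iap * self.IAP)

    @property
    def ppl0(self) -> float:
        """Pleural pressure at relaxation volume (cmH2O)."""
        return self.ppl_base + self.k_ppl * self.IAP * MMHG_TO_CMH2O

    @property
    def open_fraction(self) -> float:
        return float(self.unit_state.mean())

    # ------------------------------------------------------------------
    # mechanics primitives
    # ------------------------------------------------------------------
    def pleural_pressure(self, v: float) -> float:
        return self.ppl0 + self.ecw_eff * v

    def lung_recoil(self, veff: float) -> float:
        """Lung elastic recoil (cmH2O) at equivalent volume ``veff`` (L).

        Near-quadratic at low volumes, with an additional sharp
        stiffening above the upper inflection volume ``v_od`` (active
        only with injury).
        """
        p = self.e1_eff * veff + self.e2_eff * veff**2
        if veff > self.v_od and self.e_od_eff > 0:
            p += self.e_od_eff * (veff - self.v_od) ** 2
        return p

    def alveolar_pressure(self, v: float, f: float | None = None) -> float:
        """Static alveolar pressure at volume ``v`` (L) and open fraction ``f``."""
        if f is None:
            f = self.open_fraction
        return self.lung_recoil(v / f) + self.pleural_pressure(v)

    def equilibrium_volume(self, pressure: float, f: float | None = None) -> float:
        """Volume (L, clamped >= 0) at which alveolar pressure equals ``pressure``."""
        if f is None:
            f = self.open_fraction
        if self.alveolar_pressure(0.0, f) >= pressure:
            return 0.0
        # alveolar pressure is strictly increasing in volume: bisection
        lo, hi = 0.0, 0.5
        while self.alveolar_pressure(hi, f) < pressure:
            hi *= 2.0
            if hi > 64.0:  # pragma: no cover - unreachable for sane params
                raise ConfigurationError("equilibrium volume search diverged")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.alveolar_pressure(mid, f) < pressure:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def settle(self, peep: float, max_iter: int = 50) -> None:
        """Equilibrate recruitment state and end-expiratory volume at ``peep``.

        Applies the static opening/closing rules repeatedly until the
        unit states and volume are mutually consistent.
        """
        for _ in range(max_iter):
            v = self.equilibrium_volume(peep)
            palv = self.alveolar_pressure(v)
            new_state = self.unit_state.copy()
            new_state[self.unit_opening_pressure < palv] = True
            new_state[self.unit_closing_pressure > palv] = False
            if not new_state.any():
                # keep the most compliant unit open: a fully sealed lung
                # is outside the model's scope
                new_state[int(np.argmin(self.unit_opening_pressure))] = True
            if np.array_equal(new_state, self.unit_state):
                self.v_ee = v
                return
            self.unit_state = new_state
        self.v_ee = self.equilibrium_volume(peep)

    def pf_ratio(self) -> float:
        """PaO2/FiO2 surrogate, monotone decreasing in the closed-unit fraction.

        Combines a recruitable component (shunt through closed units)
        with a fixed injury component that recruitment cannot reverse.
        Used for injury-endpoint checks only.
        """
        recruitable = self.open_fraction ** _PF_EXPONENT
        fixed = 1.0 - _PF_FIXED_SHUNT * self.severity
        return _PF_HEALTHY * fixed * recruitable


# ----------------------------------------------------------------------
# construction and injury
# ----------------------------------------------------------------------
def make_patient(config: dict | None = None, seed: int = 0) -> VirtualPatient:
    """Build a reproducible virtual patient.

    ``config`` may override any :class:`VirtualPatient` field (unknown
    keys are rejected).  The same config and seed always produce
    bit-identical unit thresholds.  The healthy baseline is fully
    recruited at PEEP 5.
    """
    config = dict(config or {})
    config.setdefault("rng_seed", seed)
    allowed = {f for f in VirtualPatient.__dataclass_fields__ if not f.startswith("_")}
    allowed -= {"unit_opening_pressure", "unit_closing_pressure", "unit_state", "v_ee"}
    unknown = set(config) - allowed
    if unknown:
        raise ConfigurationError(f"unknown patient parameter(s): {sorted(unknown)}")
    patient = VirtualPatient(**config)
    patient.settle(peep=5.0)
    return patient


def apply_injury_and_iah(
    patient: VirtualPatient, severity: float, iap: float
) -> VirtualPatient:
    """Return a new patient with lavage-type injury and IAH applied.

    ``severity`` in [0, 1] scales the shift of the recruitment-threshold
    distribution and the lung elastances; ``iap`` (mmHg) stiffens the
    chest wall and raises the pleural baseline.  The input patient is not
    modified.  Recruitment state is settled at PEEP 5 (baseline
    ventilation), so a fully injured lung starts with a substantial
    fraction of dependent units collapsed.
    """
    if not 0 <= severity <= 1:
        raise ConfigurationError("severity must be in [0, 1]")
    if iap < 0:
        raise ConfigurationError("iap must be >= 0 mmHg")
    injured = replace(
        patient,
        severity=severity,
        IAP=iap,
        unit_opening_pressure=None,
        unit_closing_pressure=None,
        unit_state=None,
        _z=patient._z.copy(),
        _u=patient._u.copy(),
    )
    injured._set_thresholds()
    injured.unit_state = np.ones(injured.n_units, dtype=bool)
    injured.settle(peep=5.0)
    return injured


# ----------------------------------------------------------------------
# breath simulation
# ----------------------------------------------------------------------
def _simulate_occlusion(palv: float, noise: float, rng: np.random.Generator,
                        fs: float, hold_s: float = 3.0, avg_s: float = 0.2) -> float:
    """Read an occlusion pressure as the mean of the final ``avg_s`` of a hold.

    The compartment model has no stress relaxation, so the held pressure
    is constant; sensor noise is averaged down accordingly.
    """
    n_avg = max(int(avg_s * fs), 1)
    if noise > 0:
        return float(palv + rng.standard_normal(n_avg).mean() * noise)
    return float(palv)


def simulate_breath(
    patient: VirtualPatient,
    settings: VentSettings,
    sample_rate: float = 100.0,
    rng: np.random.Generator | None = None,
) -> BreathRecord:
    """Simulate one breath, updating the patient's recruitment state in place.

    VCV delivers a constant (square) inspiratory flow with 2-sample ramps
    at the transitions; PCV applies a square pressure waveform and lets
    flow follow the equation of motion.  Units open during inspiration
    when alveolar pressure exceeds their opening threshold and close at
    end-expiration when it falls below their closing threshold.
    """
    fs = sample_rate
    dt = 1.0 / fs
    if settings.t_exp <= 2 * dt:
        raise TimingError(
            f"settings imply non-positive expiratory time (rr={settings.rr}, "
            f"ie_ratio={settings.ie_ratio})"
        )
    if rng is None:
        rng = np.random.default_rng(patient.rng_seed)

    n_units = patient.n_units
    n_open0 = int(patient.unit_state.sum())
    # sorted opening thresholds of currently closed units; a pointer
    # advances through them as alveolar pressure rises
    closed_open_thr = np.sort(patient.unit_opening_pressure[~patient.unit_state])
    opened_ptr = 0

    t_insp = settings.t_insp
    t_flow = t_insp * (1.0 - settings.pause_fraction)
    period = settings.period
    n_total = int(round(period * fs))
    n_flow = max(int(round(t_flow * fs)), 4)
    n_insp = int(round(t_insp * fs))

    vt_l = settings.vt_ml_per_kg * patient.weight / 1000.0

    # start from carried end-expiratory state, re-equilibrated at PEEP
    v = max(patient.v_ee, patient.equilibrium_volume(settings.peep))
    v_start = v

    t = np.arange(n_total) * dt
    flow = np.zeros(n_total)
    paw = np.zeros(n_total)
    ppl = np.zeros(n_total)
    vol = np.zeros(n_total)

    def f_open() -> float:
        return (n_open0 + opened_ptr) / n_units

    def palv_at(vcur: float) -> float:
        return patient.alveolar_pressure(vcur, f_open())

    def recruit(vcur: float) -> float:
        """Open all units whose threshold is below alveolar pressure."""
        nonlocal opened_ptr
        palv = palv_at(vcur)
        while opened_ptr < len(closed_open_thr) and closed_open_thr[opened_ptr] < palv:
            opened_ptr += 1
            palv = palv_at(vcur)
        return palv

    if settings.mode == "VCV":
        q = vt_l / t_flow
        profile = np.full(n_flow, q)
        # two-sample linear ramps at the flow transitions
        profile[0], profile[1] = q / 3.0, 2 * q / 3.0
        profile[-1], profile[-2] = q / 3.0, 2 * q / 3.0
        for i in range(n_insp):
            fl = profile[i] if i < n_flow else 0.0
            v += fl * dt
            palv = recruit(v)
            flow[i] = fl
            paw[i] = palv + patient.Raw * fl
            ppl[i] = patient.pleural_pressure(v)
            vol[i] = v - v_start
    else:  # PCV
        p_set = settings.peep + settings.driving_pressure
        for i in range(n_insp):
            palv = recruit(v)
            fl = (p_set - palv) / patient.Raw
            fl = max(fl, 0.0)  # no expiratory valve flow during inspiration
            v += fl * dt
            palv = recruit(v)
            flow[i] = fl
            paw[i] = p_set
            ppl[i] = patient.pleural_pressure(v)
            vol[i] = v - v_start

    f_ei = f_open()
    v_ei = v
    palv_ei = palv_at(v_ei)

    # passive expiration against the set PEEP
    for i in range(n_insp, n_total):
        palv = palv_at(v)
        fl = (settings.peep - palv) / patient.Raw
        if fl > 0:
            fl = 0.0  # expiratory valve: no inflow from the circuit
        v_new = v + fl * dt
        if v_new < 0.0:
            fl = -v / dt
            v_new = 0.0
        v = v_new
        flow[i] = fl
        paw[i] = settings.peep if abs(fl) > 1e-12 else palv_at(v)
        ppl[i] = patient.pleural_pressure(v)
        vol[i] = v - v_start

    v_ee_end = v
    palv_ee = palv_at(v_ee_end)

    # occlusion readings (3-s zero-flow holds, mean of final 0.2 s)
    pplat = _simulate_occlusion(palv_ei, patient.noise_sigma, rng, fs)
    total_peep = _simulate_occlusion(palv_ee, patient.noise_sigma, rng, fs)
    ppl_ei = patient.pleural_pressure(v_ei)
    ppl_ee = patient.pleural_pressure(v_ee_end)

    if patient.noise_sigma > 0:
        paw = paw + rng.standard_normal(n_total) * patient.noise_sigma
        ppl = ppl + rng.standard_normal(n_total) * patient.noise_sigma

    # update patient state: recruitment gained during the breath, then
    # end-expiratory closure (gas in closing units is expelled)
    if opened_ptr > 0:
        idx = np.where(~patient.unit_state)[0]
        order = np.argsort(patient.unit_opening_pressure[idx])
        patient.unit_state[idx[order[:opened_ptr]]] = True
    f_before = patient.open_fraction
    closing = patient.unit_state & (patient.unit_closing_pressure > palv_ee)
    if closing.any():
        if closing.sum() == patient.unit_state.sum():
            # keep the unit with the lowest closing pressure open: a
            # fully sealed lung is outside the model's scope
            open_idx = np.where(patient.unit_state)[0]
            keep = open_idx[int(np.argmin(patient.unit_closing_pressure[open_idx]))]
            closing[keep] = False
        patient.unit_state[closing] = False
        f_after = patient.open_fraction
        v_ee_end *= f_after / f_before
    patient.v_ee = v_ee_end

    return BreathRecord(
        t=t, flow=flow, paw=paw, ppl=ppl, volume=vol * 1000.0,
        pplat=pplat, total_peep=total_peep,
        ppl_ei=ppl_ei, ppl_ee=ppl_ee,
        sample_rate=fs, vt_ml=(v_ei - v_start) * 1000.0,
    )


def run_ventilation(
    patient: VirtualPatient,
    settings: VentSettings,
    duration: float,
    sample_rate: float = 100.0,
    rng: np.random.Generator | None = None,
) -> list[BreathRecord]:
    """Simulate ``duration`` seconds of ventilation breath by breath.

    The patient's recruitment and volume state advance across breaths;
    the number of breaths is ``floor(duration / period)``.
    """
    if duration < settings.period:
        raise TimingError("duration must cover at least one breath period")
    if rng is None:
        rng = np.random.default_rng(patient.rng_seed)
    n_breaths = int(duration / settings.period)
    return [simulate_breath(patient, settings, sample_rate, rng) for _ in range(n_breaths)]


# ----------------------------------------------------------------------
# frozen study fixtures
# ----------------------------------------------------------------------
def overdistension_fixture(seed: int = 1) -> tuple[VirtualPatient, VentSettings]:
    """Fully recruited lung operated above its upper inflection point.

    A healthy (fully recruited) patient with a large volume-dependent
    elastance, ventilated with a generous tidal volume at moderate PEEP:
    the pressure-time curve is convex upward and the stress index
    exceeds the overdistension threshold.
    """
    patient = make_patient({"E2": 40.0}, seed=seed)
    settings = VentSettings(mode="VCV", vt_ml_per_kg=10.0, rr=20.0, peep=10.0)
    patient.settle(settings.peep)
    return patient, settings


def recruitment_fixture(seed: int = 1) -> tuple[VirtualPatient, VentSettings]:
    """Injured lung at low PEEP with thresholds inside the tidal range.

    Full-severity injury without IAH, ventilated at PEEP 2: many unit
    opening pressures lie inside the tidal pressure excursion, units
    recruit throughout inspiration, the pressure-time curve is concave
    downward and the stress index falls below the tidal-recruitment
    threshold.
    """
    patient = apply_injury_and_iah(make_patient(seed=seed), severity=1.0, iap=0.0)
    settings = VentSettings(mode="VCV", vt_ml_per_kg=10.0, rr=20.0, peep=2.0)
    patient.settle(settings.peep)
    return patient, settings


def default_study_patient(seed: int = 1) -> VirtualPatient:
    """The frozen default injured + IAH subject of the simulated study.

    Full-severity lavage-type injury with IAP 26 mmHg (mid-range of the
    25-27 mmHg study condition) on the default 32-kg patient.
    """
    return apply_injury_and_iah(make_patient(seed=seed), severity=1.0, iap=26.0)
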