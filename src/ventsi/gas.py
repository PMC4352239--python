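"""Single-compartment CO2 kinetics and acid-base state.

Arterial CO2 is tracked as a well-mixed body store with production
``VCO2`` (ml/min STPD) and alveolar elimination proportional to
``PaCO2 * VA``.  At steady state this reproduces the classical alveolar
ventilation relation

    PaCO2 = 0.863 * VCO2 / VA        (mmHg, VCO2 ml/min, VA L/min)

and relaxes toward it first-order with time constant
``capacity / (k_el * VA)`` where ``k_el = 1/0.863`` and ``capacity``
(ml STPD per mmHg) is the slope of the body CO2 store.  pH follows
Henderson-Hasselbalch with a fixed metabolic bicarbonate (acute
experiment, no renal compensation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .patient import VentSettings, VirtualPatient

#: Alveolar ventilation constant: PaCO2 = K_ALV * VCO2 / VA.
K_ALV = 0.863
K_EL = 1.0 / K_ALV


@dataclass(frozen=True)
class GasState:
    """Arterial gas and acid-base state."""

    paco2: float            # mmHg
    ph: float
    pao2_fio2: float        # mmHg
    co2_store: float        # ml STPD above zero-PaCO2 reference


def ph_from_paco2(paco2: float, hco3: float = 24.0) -> float:
    """Henderson-Hasselbalch: pH = 6.1 + log10(HCO3 / (0.03 * PaCO2))."""
    if paco2 <= 0:
        raise ConfigurationError("paco2 must be > 0")
    return 6.1 + math.log10(hco3 / (0.03 * paco2))


def alveolar_ventilation(settings: VentSettings, patient: VirtualPatient) -> float:
    """Alveolar ventilation VA = RR * (VT - VD) / 1000 (L/min).

    Returns 0 with a warning when the tidal volume does not clear the
    airway dead space.
    """
    vt_ml = settings.vt_ml_per_kg * patient.weight
    if vt_ml <= patient.vd_aw:
        warnings.warn(
            f"tidal volume {vt_ml:.0f} ml does not exceed dead space "
            f"{patient.vd_aw:.0f} ml; alveolar ventilation is zero",
            stacklevel=2,
        )
        return 0.0
    return settings.rr * (vt_ml - patient.vd_aw) / 1000.0


def steady_state_paco2(vco2: float, va: float) -> float:
    """Steady-state PaCO2 (mmHg) for production ``vco2`` and ventilation ``va``."""
    if va <= 0:
        return math.inf
    return K_ALV * vco2 / va


def initial_gas_state(patient: VirtualPatient, settings: VentSettings) -> GasState:
    """Gas state at the steady state of the given ventilation."""
    va = alveolar_ventilation(settings, patient)
    paco2 = steady_state_paco2(patient.vco2, va)
    return GasState(
        paco2=paco2,
        ph=ph_from_paco2(paco2, patient.hco3),
        pao2_fio2=patient.pf_ratio(),
        co2_store=patient.co2_capacity * paco2,
    )


def co2_step(patient: VirtualPatient, gas: GasState, va: float, dt: float) -> GasState:
    """Advance the CO2 store by ``dt`` seconds at alveolar ventilation ``va``.

    Uses the exact exponential solution of the linear store balance
    d(store)/dt = VCO2 - k_el * PaCO2 * VA with PaCO2 = store/capacity,
    so repeated small steps and one large step agree to rounding.  With
    ``va == 0`` PaCO2 grows linearly without bound (apnoea).
    """
    if va < 0:
        raise ConfigurationError("va must be >= 0")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    dt_min = dt / 60.0
    cap = patient.co2_capacity
    if va == 0:
        paco2 = gas.paco2 + patient.vco2 * dt_min / cap
    else:
        target = steady_state_paco2(patient.vco2, va)
        rate = K_EL * va / cap  # 1/min
        paco2 = target + (gas.paco2 - target) * math.exp(-rate * dt_min)
    return replace(
        gas,
        paco2=paco2,
        ph=ph_from_paco2(paco2, patient.hco3),
        co2_store=cap * paco2,
        pao2_fio2=patient.pf_ratio(),
    )
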