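"""Stress-index fit: oracle equivalence, parameter recovery, edge cases."""

import numpy as np
import pytest

from ventsi import (
    ConstantFlowError,
    TruncatedTraceError,
    UndefinedComplianceError,
    VentSettings,
    classify_si,
    compute_mechanics,
    detect_auto_peep,
    extract_constant_flow_window,
    fit_stress_index,
    make_patient,
    overdistension_fixture,
    recruitment_fixture,
    simulate_breath,
)

from conftest import grid_search_power_fit, synthetic_power_breath


def _window_arrays(breath):
    t0, t1 = extract_constant_flow_window(breath)
    mask = (breath.t >= t0) & (breath.t <= t1)
    t = np.asarray(breath.t[mask], float) - t0
    p = np.asarray(breath.paw[mask] - breath.ppl[mask], float)
    return t, p


@pytest.mark.parametrize("b_true", [0.7, 1.0, 1.3])
def test_fit_matches_brute_force_grid_oracle(b_true):
    """NLS fit attains an RSS within 1e-6 of an exhaustive b-grid search."""
    breath = synthetic_power_breath(a=12.0, b=b_true, c=6.0,
                                    noise_sigma=0.1, rng=np.random.default_rng(5))
    fit = fit_stress_index(breath)
    t, p = _window_arrays(breath)
    assert len(t) <= 200
    *_, rss_grid = grid_search_power_fit(t, p, np.arange(0.3, 3.0, 0.001))
    assert fit.rss <= rss_grid + 1e-6


@pytest.mark.parametrize("fixture", [overdistension_fixture, recruitment_fixture])
def test_fit_matches_grid_oracle_on_simulated_breaths(fixture):
    patient, settings = fixture(seed=1)
    breath = simulate_breath(patient, settings)
    fit = fit_stress_index(breath)
    t, p = _window_arrays(breath)
    *_, rss_grid = grid_search_power_fit(t, p, np.arange(0.3, 3.0, 0.001))
    assert fit.rss <= rss_grid + 1e-6


def test_exponent_recovery_under_noise():
    """200 noisy synthetic breaths: median |b - b*| < 0.02, p95 < 0.05."""
    rng = np.random.default_rng(42)
    errors = []
    for _ in range(200):
        b_true = rng.uniform(0.7, 1.4)
        breath = synthetic_power_breath(a=12.0, b=b_true, c=6.0,
                                        noise_sigma=0.1, rng=rng)
        fit = fit_stress_index(breath)
        errors.append(abs(fit.b - b_true))
    errors = np.array(errors)
    assert float(np.median(errors)) < 0.02
    assert float(np.quantile(errors, 0.95)) < 0.05


def test_fit_is_scale_equivariant():
    breath = synthetic_power_breath(a=10.0, b=1.2, c=5.0)
    fit1 = fit_stress_index(breath)
    scale = 3.7
    scaled = synthetic_power_breath(a=10.0 * scale, b=1.2, c=5.0 * scale)
    fit2 = fit_stress_index(scaled)
    assert fit2.b == pytest.approx(fit1.b, abs=1e-6)
    assert fit2.a == pytest.approx(scale * fit1.a, rel=1e-5)
    assert fit2.c == pytest.approx(scale * fit1.c, rel=1e-5)


def test_classification_band_is_closed():
    assert classify_si(0.95) == "non_injurious"
    assert classify_si(1.05) == "non_injurious"
    assert classify_si(1.0) == "non_injurious"
    assert classify_si(0.9499) == "tidal_recruitment"
    assert classify_si(1.0501) == "overdistension"


def test_airway_signal_option():
    breath = synthetic_power_breath(a=12.0, b=1.1, c=6.0)
    fit_tp = fit_stress_index(breath, signal="transpulmonary")
    fit_aw = fit_stress_index(breath, signal="airway")
    # zero pleural pressure in the synthetic record: both signals agree
    assert fit_aw.b == pytest.approx(fit_tp.b, abs=1e-9)


def test_decelerating_flow_has_no_constant_window():
    patient = make_patient(seed=1)
    settings = VentSettings(mode="PCV", rr=20.0, peep=5.0,
                            driving_pressure=15.0, vt_ml_per_kg=8.0)
    breath = simulate_breath(patient, settings)
    with pytest.raises(ConstantFlowError):
        extract_constant_flow_window(breath)


def test_auto_peep_detection():
    full = synthetic_power_breath(a=12.0, b=1.0, c=6.0)
    assert detect_auto_peep(full) is False

    # truncate the expiration: flow still clearly negative at the end
    n = len(full.t) - 120
    from ventsi import BreathRecord

    short = BreathRecord(
        t=full.t[:n], flow=full.flow[:n], paw=full.paw[:n],
        ppl=full.ppl[:n], volume=full.volume[:n],
        pplat=full.pplat, total_peep=full.total_peep,
        ppl_ei=full.ppl_ei, ppl_ee=full.ppl_ee,
        sample_rate=full.sample_rate, vt_ml=full.vt_ml,
    )
    assert detect_auto_peep(short) is True

    insp_only = BreathRecord(
        t=full.t[:100], flow=full.flow[:100], paw=full.paw[:100],
        ppl=full.ppl[:100], volume=full.volume[:100],
        pplat=full.pplat, total_peep=full.total_peep,
        ppl_ei=full.ppl_ei, ppl_ee=full.ppl_ee,
        sample_rate=full.sample_rate, vt_ml=full.vt_ml,
    )
    with pytest.raises(TruncatedTraceError):
        detect_auto_peep(insp_only)


def test_undefined_compliance_names_denominator():
    breath = synthetic_power_breath(a=12.0, b=1.0, c=6.0)
    # force Pplat == total PEEP so the crs denominator vanishes
    from dataclasses import replace as _  # noqa: F401
    from ventsi import BreathRecord

    degenerate = BreathRecord(
        t=breath.t, flow=breath.flow, paw=breath.paw, ppl=breath.ppl,
        volume=breath.volume, pplat=6.0, total_peep=6.0,
        ppl_ei=0.0, ppl_ee=0.0, sample_rate=breath.sample_rate,
        vt_ml=breath.vt_ml,
    )
    with pytest.raises(UndefinedComplianceError, match="crs"):
        compute_mechanics(degenerate, degenerate.vt_ml)
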