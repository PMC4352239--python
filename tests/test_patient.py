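"""Virtual-patient simulator: determinism, hysteresis, coupling, conservation."""

import copy

import numpy as np
import pytest

from ventsi import (
    ConfigurationError,
    TimingError,
    VentSettings,
    apply_injury_and_iah,
    compute_mechanics,
    default_study_patient,
    make_patient,
    simulate_breath,
)


def test_same_seed_gives_identical_patients():
    p1 = make_patient(seed=7)
    p2 = make_patient(seed=7)
    np.testing.assert_array_equal(p1.unit_opening_pressure, p2.unit_opening_pressure)
    np.testing.assert_array_equal(p1.unit_closing_pressure, p2.unit_closing_pressure)
    s = VentSettings(mode="VCV", vt_ml_per_kg=8.0, rr=20.0, peep=5.0)
    b1 = simulate_breath(p1, s)
    b2 = simulate_breath(p2, s)
    np.testing.assert_array_equal(b1.paw, b2.paw)
    np.testing.assert_array_equal(b1.volume, b2.volume)


def test_different_seeds_differ():
    p1 = make_patient(seed=1)
    p2 = make_patient(seed=2)
    assert not np.array_equal(p1.unit_opening_pressure, p2.unit_opening_pressure)


@pytest.mark.parametrize("builder", [
    lambda: make_patient(seed=3),
    lambda: default_study_patient(seed=3),
])
def test_unit_hysteresis_closing_below_opening(builder):
    p = builder()
    assert np.all(p.unit_closing_pressure < p.unit_opening_pressure)


def test_iah_stiffens_chest_wall_monotonically():
    base = make_patient(seed=1)
    ccw = []
    for iap in (0.0, 10.0, 20.0, 26.0):
        p = apply_injury_and_iah(base, severity=0.0, iap=iap)
        ccw.append(1000.0 / p.ecw_eff)  # ml/cmH2O
    assert all(a > b for a, b in zip(ccw, ccw[1:]))


def test_iah_raises_pleural_baseline():
    base = make_patient(seed=1)
    p0 = apply_injury_and_iah(base, severity=0.0, iap=0.0)
    p1 = apply_injury_and_iah(base, severity=0.0, iap=26.0)
    assert p1.ppl0 > p0.ppl0


def test_injury_and_iah_compliance_drops_in_band(healthy_patient):
    """Ccw falls ~57% and C_L ~62% (each within +/-10 points) vs healthy."""
    settings = VentSettings(mode="VCV", vt_ml_per_kg=8.0, rr=20.0, peep=5.0)

    healthy = copy.deepcopy(healthy_patient)
    bh = simulate_breath(healthy, settings)
    mh = compute_mechanics(bh, bh.vt_ml)

    injured = default_study_patient(seed=1)
    bi = simulate_breath(injured, settings)
    mi = compute_mechanics(bi, bi.vt_ml)

    ccw_drop = 100.0 * (1.0 - mi.ccw / mh.ccw)
    cl_drop = 100.0 * (1.0 - mi.cl / mh.cl)
    assert 47.0 <= ccw_drop <= 67.0
    assert 52.0 <= cl_drop <= 72.0


def test_injury_collapses_dependent_units(injured_patient):
    assert injured_patient.open_fraction < 0.7
    healthy = make_patient(seed=1)
    assert healthy.open_fraction > 0.99


def test_volume_conservation_within_breath(injured_patient):
    settings = VentSettings(mode="VCV", vt_ml_per_kg=8.0, rr=20.0, peep=10.0)
    b = simulate_breath(injured_patient, settings)
    # delivered tidal volume equals the commanded volume
    # small deficit from the discrete flow ramps at the sample rate
    assert b.vt_ml == pytest.approx(8.0 * injured_patient.weight, rel=0.03)
    # lung volume never negative, and its rise tracks the flow integral
    assert np.all(b.volume >= -1e-9)
    dt = 1.0 / b.sample_rate
    integral_ml = float(np.sum(b.flow[b.flow > 0]) * dt * 1000.0)
    rise_ml = float(b.volume.max() - b.volume[0])
    assert rise_ml == pytest.approx(integral_ml, rel=0.05)


def test_equilibrium_volume_monotone_in_peep(injured_patient):
    vols = [injured_patient.equilibrium_volume(p) for p in (0.0, 5.0, 10.0, 15.0, 20.0)]
    assert all(b >= a - 1e-12 for a, b in zip(vols, vols[1:]))


def test_end_expiratory_volume_floor_at_zero():
    p = default_study_patient(seed=1)
    p.settle(0.0)
    assert p.v_ee >= 0.0


def test_recruitment_maneuver_reopens_lung(injured_patient):
    from ventsi import recruitment_maneuver

    recruitment_maneuver(injured_patient)
    injured_patient.settle(20.0)
    assert injured_patient.open_fraction > 0.95


def test_invalid_settings_rejected():
    with pytest.raises((TimingError, ConfigurationError)):
        VentSettings(mode="VCV", vt_ml_per_kg=8.0, rr=0.0, peep=5.0)
    with pytest.raises((TimingError, ConfigurationError)):
        VentSettings(mode="VCV", vt_ml_per_kg=-1.0, rr=20.0, peep=5.0)


def test_make_patient_rejects_unknown_keys():
    with pytest.raises(ConfigurationError):
        make_patient({"not_a_field": 1.0}, seed=1)


def test_pf_ratio_falls_with_derecruitment(injured_patient):
    healthy = make_patient(seed=1)
    assert injured_patient.pf_ratio() < healthy.pf_ratio()
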