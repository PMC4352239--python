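"""Shared fixtures and synthetic-breath helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ventsi import (
    BreathRecord,
    default_study_patient,
    make_patient,
)

SAMPLE_RATE = 100.0


def synthetic_power_breath(
    a: float,
    b: float,
    c: float,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    t_insp: float = 1.0,
    sample_rate: float = SAMPLE_RATE,
    flow: float = 0.3,
) -> BreathRecord:
    """Analytic constant-flow breath whose fit window obeys P = a*t^b + c.

    The inspiratory pressure follows the power law with time re-zeroed
    at the start of the fitted window (the analyser skips the first 5%
    of the inspiration), so the generating exponent ``b`` is exactly
    the quantity the fit should recover.  A short pause and a decaying
    expiration complete the record.
    """
    dt = 1.0 / sample_rate
    n_insp = int(round(t_insp * sample_rate))
    t_ins = np.arange(n_insp) * dt
    # window start used by the analyser: 5% of the inspiratory span
    t_skip = 0.05 * (t_ins[-1] - t_ins[0])
    tau = np.clip(t_ins - t_skip, 0.0, None)
    p_ins = a * np.power(tau, b) + c
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        p_ins = p_ins + rng.normal(0.0, noise_sigma, size=n_insp)

    n_pause = int(round(0.3 * sample_rate))
    n_exp = int(round(1.5 * sample_rate))
    t_pause = t_ins[-1] + dt + np.arange(n_pause) * dt
    t_exp = t_pause[-1] + dt + np.arange(n_exp) * dt
    p_end = a * (t_ins[-1] - t_skip) ** b + c
    q_exp = -flow * np.exp(-np.arange(n_exp) * dt / 0.2)

    t = np.concatenate([t_ins, t_pause, t_exp])
    q = np.concatenate([np.full(n_insp, flow), np.zeros(n_pause), q_exp])
    paw = np.concatenate([
        p_ins,
        np.full(n_pause, p_end),
        c + (p_end - c) * np.exp(-np.arange(n_exp) * dt / 0.2),
    ])
    vol_ins = np.cumsum(np.full(n_insp, flow)) * dt * 1000.0
    vt = vol_ins[-1]
    vol = np.concatenate([
        vol_ins,
        np.full(n_pause, vt),
        vt * np.exp(-np.arange(n_exp) * dt / 0.2),
    ])
    return BreathRecord(
        t=t, flow=q, paw=paw, ppl=np.zeros_like(t), volume=vol,
        pplat=p_end, total_peep=c, ppl_ei=0.0, ppl_ee=0.0,
        sample_rate=sample_rate, vt_ml=vt,
    )


def grid_search_power_fit(
    t: np.ndarray, p: np.ndarray, b_grid: np.ndarray
) -> tuple[float, float, float, float]:
    """Brute-force oracle for the power fit.

    For each candidate exponent b, (a, c) follow from linear least
    squares on the basis [t^b, 1]; returns (a, b, c, rss) at the grid
    minimum.
    """
    best = (np.nan, np.nan, np.nan, np.inf)
    ones = np.ones_like(t)
    for b in b_grid:
        basis = np.column_stack([np.power(t, b), ones])
        coef, *_ = np.linalg.lstsq(basis, p, rcond=None)
        resid = p - basis @ coef
        rss = float(resid @ resid)
        if rss < best[3]:
            best = (float(coef[0]), float(b), float(coef[1]), rss)
    return best


@pytest.fixture(scope="session")
def healthy_patient():
    return make_patient(seed=1)


@pytest.fixture()
def injured_patient():
    return default_study_patient(seed=1)
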