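"""Synthetic CT phantom and Hounsfield-unit aeration classification.

Lung aeration on CT is classified into four density compartments:
nonaerated (-100 to +100 HU), poorly aerated (-500 to -100 HU),
normally aerated (-900 to -500 HU) and overinflated (-1000 to -900 HU).
Shared boundaries are owned by the more aerated class (half-open
intervals toward -1000); densities outside [-1000, +100] are non-lung.

The phantom maps the virtual patient's aeration state onto a small
3-D grid: four anatomical levels (aortic arch, heart, main bronchi,
above diaphragm), each a 64 x 64 slice split into ventral and dorsal
regions of interest (ROIs).  Voxel HU is derived from gas fraction as
``HU = -1000 * gas_fraction`` plus tissue noise; closed units are
assigned preferentially to the dorsal ROI, emulating collapse in
gravity-dependent regions.  Per-region compartment percentages are
reported against a 10% clinical-significance threshold (the normally
aerated compartment is never flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patient import VirtualPatient

HU_RANGE = (-1024.0, 3071.0)
LUNG_WINDOW = (-1000.0, 100.0)
#: Compartment boundaries (cmH2O-free HU edges, more aerated side owns the edge)
EDGE_OVER = -900.0
EDGE_NORMAL = -500.0
EDGE_POOR = -100.0

LEVEL_NAMES = {1: "aortic arch", 2: "heart", 3: "main bronchi", 4: "above diaphragm"}
COMPARTMENTS = ("overinflated", "normally_aerated", "poorly_aerated", "nonaerated")

#: Gas fractions used by the phantom renderer.
_GAS_FRACTION_NONAERATED = 0.06
_GAS_FRACTION_FRC = 0.62        # normally aerated lung at end-expiration
_GAS_LINEAR_GAIN = 0.12         # mild rise of gas fraction with distension
_GAS_LINEAR_HALF = 0.5          # L
_GAS_OVER_GAIN = 0.25           # sharp rise above the overinflation knee
_GAS_OVER_CENTER = 0.45         # L equivalent volume
_GAS_OVER_WIDTH = 0.045         # L
_TISSUE_NOISE_HU = 18.0
_DORSAL_PREFERENCE = 0.85       # weight steering closed units dorsally


@dataclass
class HUVolume:
    """Labelled synthetic HU volume: (level, row, column) voxel grid."""

    voxels: np.ndarray          # (n_levels, ny, nx) HU values
    level_labels: np.ndarray    # (n_levels,) ints in 1..4
    roi_labels: np.ndarray      # (n_levels, ny, nx) strings 'ventral'/'dorsal'
    voxel_size: float = 3.0     # mm

    def __post_init__(self) -> None:
        lung = (self.voxels >= HU_RANGE[0]) & (self.voxels <= HU_RANGE[1])
        if not lung.all():
            raise ValueError("HU values outside the CT range")


@dataclass
class AerationReport:
    """Per-(level, ROI) compartment percentages and significance flags."""

    table: pd.DataFrame  # columns: level, roi, <compartment>_pct..., flags
    threshold_pct: float


def classify_voxel(hu: float) -> str:
    """Classify one HU value into an aeration compartment.

    Boundaries are half-open toward the more aerated class:
    overinflated [-1000, -900], normally aerated (-900, -500],
    poorly aerated (-500, -100], nonaerated (-100, +100].
    Values outside [-1000, +100] are 'non_lung'.
    """
    if hu < LUNG_WINDOW[0] or hu > LUNG_WINDOW[1]:
        return "non_lung"
    if hu <= EDGE_OVER:
        return "overinflated"
    if hu <= EDGE_NORMAL:
        return "normally_aerated"
    if hu <= EDGE_POOR:
        return "poorly_aerated"
    return "nonaerated"


def classify_volume(voxels: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_voxel`; returns an object array of labels."""
    v = np.asarray(voxels, dtype=float)
    out = np.full(v.shape, "non_lung", dtype=object)
    lung = (v >= LUNG_WINDOW[0]) & (v <= LUNG_WINDOW[1])
    out[lung & (v <= EDGE_OVER)] = "overinflated"
    out[lung & (v > EDGE_OVER) & (v <= EDGE_NORMAL)] = "normally_aerated"
    out[lung & (v > EDGE_NORMAL) & (v <= EDGE_POOR)] = "poorly_aerated"
    out[lung & (v > EDGE_POOR)] = "nonaerated"
    return out


def render_phantom(
    patient: VirtualPatient,
    mode: str = "end_expiration",
    seed: int = 0,
    vt_ml: float | None = None,
    shape: tuple[int, int, int] = (4, 64, 64),
) -> HUVolume:
    """Render a deterministic HU phantom from the patient's aeration state.

    Closed units become nonaerated voxels, assigned preferentially to
    the dorsal ROI.  Open voxels receive a gas fraction built from the
    resting fraction plus the current distension (``Veff``); in
    ``end_inspiration`` mode the tidal volume ``vt_ml`` (default
    8 ml/kg) is added on top of the end-expiratory volume.
    """
    if mode not in ("end_expiration", "end_inspiration"):
        raise ValueError(f"unknown phantom mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_levels, ny, nx = shape

    f = patient.open_fraction
    closed_frac = 1.0 - f
    v = patient.v_ee
    if mode == "end_inspiration":
        if vt_ml is None:
            vt_ml = 8.0 * patient.weight
        v = v + vt_ml / 1000.0
    veff = v / f if f > 0 else 0.0
    # open-voxel gas fraction: resting value, a mild distension term and
    # a sharp logistic rise once the equivalent volume passes the
    # overinflation knee
    gas_open = (
        _GAS_FRACTION_FRC
        + _GAS_LINEAR_GAIN * veff / (veff + _GAS_LINEAR_HALF)
        + _GAS_OVER_GAIN / (1.0 + np.exp(-(veff - _GAS_OVER_CENTER) / _GAS_OVER_WIDTH))
    )
    gas_open = min(gas_open, 0.98)

    voxels = np.empty(shape)
    roi = np.empty(shape, dtype=object)
    level_labels = np.arange(1, n_levels + 1)
    ventral_rows = ny // 2

    for lv in range(n_levels):
        # dorsal depth in [0, 1); dorsal half has depth >= 0.5
        depth = np.tile(np.linspace(0.0, 1.0, ny, endpoint=False)[:, None], (1, nx))
        roi[lv] = np.where(depth < 0.5, "ventral", "dorsal")
        # rank voxels by dorsal preference with jitter; the closed_frac
        # highest-ranked voxels are nonaerated
        jitter = rng.random((ny, nx))
        rank = _DORSAL_PREFERENCE * depth + (1.0 - _DORSAL_PREFERENCE) * jitter
        cutoff = np.quantile(rank, 1.0 - closed_frac) if closed_frac > 0 else np.inf
        closed_mask = rank >= cutoff if closed_frac > 0 else np.zeros((ny, nx), bool)
        gas = np.where(closed_mask, _GAS_FRACTION_NONAERATED, gas_open)
        hu = -1000.0 * gas + rng.standard_normal((ny, nx)) * _TISSUE_NOISE_HU
        voxels[lv] = np.clip(hu, *HU_RANGE)

    return HUVolume(voxels=voxels, level_labels=level_labels, roi_labels=roi)


def roi_report(volume: HUVolume, threshold_pct: float = 10.0) -> AerationReport:
    """Compartment percentages per (level, ROI) with significance flags.

    Percentages are over lung voxels (HU within [-1000, +100]) in the
    region; a compartment is flagged when its percentage reaches
    ``threshold_pct``, except the normally aerated compartment, which
    is never flagged.  Regions without lung voxels are omitted with a
    warning.
    """
    labels = classify_volume(volume.voxels)
    rows = []
    for lv_idx, level in enumerate(volume.level_labels):
        for roi_name in ("ventral", "dorsal"):
            mask = volume.roi_labels[lv_idx] == roi_name
            region = labels[lv_idx][mask]
            lung = region != "non_lung"
            n_lung = int(lung.sum())
            if n_lung == 0:
                warnings.warn(
                    f"level {level} {roi_name}: no lung voxels; region omitted",
                    stacklevel=2,
                )
                continue
            row = {"level": int(level), "roi": roi_name}
            for comp in COMPARTMENTS:
                pct = 100.0 * float((region == comp).sum()) / n_lung
                row[f"{comp}_pct"] = pct
                if comp == "normally_aerated":
                    row[f"{comp}_flag"] = False
                else:
                    row[f"{comp}_flag"] = pct >= threshold_pct
            rows.append(row)
    return AerationReport(table=pd.DataFrame(rows), threshold_pct=threshold_pct)
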