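# Methods

This note documents the model, the numerical choices and the design
decisions behind `ventsi`.  Units are cmH₂O, litres (or ml where stated),
seconds, mmHg for blood gases and intra-abdominal pressure (IAP).

## 1. Virtual patient

### 1.1 Lung units and recruitment hysteresis

The lung is a population of `n_units = 500` parallel units.  Each unit `i`
carries an opening pressure `P_open,i` and a closing pressure
`P_close,i < P_open,i` (hysteresis).  A closed unit opens when alveolar
pressure exceeds `P_open,i` during inspiration; an open unit closes when
end-expiratory alveolar pressure falls below `P_close,i`.  When units close
at end-expiration, the gas they contained is expelled (the lung volume is
scaled by the ratio of open fractions), which produces the characteristic
derecruitment-induced loss of end-expiratory volume.

Thresholds are drawn once per subject from a seeded generator:

| quantity | healthy | full injury |
|---|---|---|
| closing pressure | N(1.0, 0.5) | N(10, 4), floor 0.3 |
| opening − closing gap | 2.0 | 8 + U[0, 20] |

with opening pressures clipped to [1, 45] cmH₂O and severity interpolating
linearly between the columns.  Rationale: the closing distribution sets
*where* decremental derecruitment begins (≈ 13 cmH₂O and below at full
injury), the heterogeneous gap sets *how wide* the tidal-recruitment zone
is at low PEEP, and the clip guarantees a 50-cmH₂O recruitment maneuver
reopens everything.  A unimodal opening distribution with a fixed gap was
tried first and rejected: its heavy closing-pressure tail left ~20% of
units cycling at any clinically reachable PEEP, so no tidal volume could
ever bring the stress index into the neutral band.

### 1.2 Pressures

With `V` the lung volume above relaxation volume, `f` the open fraction and
`V_eff = V / f` the volume concentrated in open units:

- lung recoil: `P_L = E1·V_eff + E2·V_eff² + E_od·max(V_eff − V_od, 0)²`
- pleural pressure: `P_pl = ppl0 + Ecw_eff · V`
- alveolar pressure: `P_alv = P_L + P_pl`
- airway pressure: `P_aw = P_alv + Raw · flow`

The third recoil term is an injury-activated **upper inflection**
(`E_od = severity · 450 cmH₂O/L²` above `V_od = 0.30 L`).  Without it a
quadratic recoil is convex everywhere and the pressure–time curve shows
`b > 1` at every tidal volume, so no SI-guided titration can terminate; with
it the curve is near-linear below the knee and stiffens sharply above,
which is the physiological overdistension regime.  A healthy subject
(`severity = 0`) keeps the plain `E1·V + E2·V²` recoil.

Injury scales the elastances: `E1_eff = E1·(1 + severity)`,
`E2_eff = E2·(1 + 4·severity)`.

### 1.3 Intra-abdominal hypertension

IAH couples in twice:

- chest wall: `Ecw_eff = Ecw_base · (1 + k_iap · IAP)` with
  `k_iap = 0.051 /mmHg`, chosen so chest-wall compliance falls by exactly
  57% at IAP 26 mmHg;
- pleural baseline: `ppl0 = ppl_base + k_ppl · IAP · 1.36` with
  `k_ppl = 0.25` (1.36 converts mmHg to cmH₂O).  A larger transmission
  fraction (0.5, i.e. ≈ 18 cmH₂O at IAP 26) was tried and rejected: it
  clamps the end-expiratory volume at the airway-closure floor for every
  PEEP of interest and flattens the compliance–PEEP relation, making a
  decremental titration meaningless.  0.25 gives end-expiratory pleural
  pressures of ≈ 10–12 cmH₂O at open-lung PEEP, which is physiologically
  plausible for severe IAH.

### 1.4 Breaths

VCV delivers a square flow (with two-sample ramps to avoid discretization
spikes) followed by an end-inspiratory pause; PCV applies a square pressure
with flow `(P_set − P_alv)/Raw`.  Expiration is passive
(explicit-Euler relaxation against the ventilator PEEP, volume clamped at
zero — the airway-closure floor).  Units recruit sample-by-sample during
inspiration as alveolar pressure crosses their opening thresholds.
Occlusion readings (plateau pressure, total PEEP and the simultaneous
pleural pressures) are simulated as 3-s static holds, averaging the final
0.2 s.  Auto-PEEP is flagged when expiratory flow still exceeds 0.01 L/s at
the instant the next breath would start.

### 1.5 Default subject

32 kg; `E1 = 21.5`, `E2 = 2.0 cmH₂O/L(²)`, `Raw = 10 cmH₂O/(L/s)`,
`Ecw_base = 12.5 cmH₂O/L` (chest-wall compliance 80 ml/cmH₂O),
FRC 900 ml.  The frozen study subject is `severity = 1.0`, `IAP = 26 mmHg`.
These values reproduce component compliance drops of 57% (chest wall) and
≈ 65% (lung) versus healthy.  Note that respiratory-system, lung and
chest-wall compliances are bound by `1/Crs = 1/C_L + 1/Ccw`; a physically
consistent model cannot impose all three drops independently, so the
simulator calibrates the two components and lets `Crs` follow (≈ 63% drop).

## 2. Waveform analysis

The constant-flow window is the maximal contiguous run of samples within 2%
of the median inspiratory flow, after discarding the first 5% of the
inspiration; decelerating-flow (PCV) breaths raise `ConstantFlowError`.
The stress index is fitted as `P(t) = a·t^b + c` with time re-zeroed at the
window start, via bounded nonlinear least squares (`b ∈ [0.3, 3.0]`, four
perturbed restarts).  The default fitted signal is **transpulmonary**
pressure (`P_aw − P_pl`), the appropriate choice under IAH; raw airway
pressure is available as an option.  The test-suite oracle verifies the fit
against a brute-force grid search over `b` (step 0.001) with linear least
squares for `a, c` at each grid point.

Static mechanics from the occlusions: `Crs = VT/(Pplat − totalPEEP)`,
`C_L = VT/ΔP_TP`, `Ccw = VT/ΔP_pl`; a non-positive denominator raises
`UndefinedComplianceError` naming the offending compliance.

## 3. Gas exchange

Alveolar ventilation `VA = RR·(VT − VD)/1000` (series dead space
`VD = 77 ml`).  Steady state obeys `PaCO2 = 0.863 · VCO2 / VA`
(`VCO2 = 200 ml/min` default).  Dynamics use a single well-mixed CO₂ store
(capacity 64 ml/mmHg) with elimination `VA·PaCO2/0.863`, integrated with
the **exact exponential** solution so step subdivision is irrelevant
(verified to 1e-9).  pH follows Henderson–Hasselbalch with fixed
bicarbonate 24 mmol/L — metabolic compensation is deliberately out of
scope on a 4-hour horizon.  Oxygenation is a descriptive P/F surrogate
`515 · (1 − 0.5·severity) · f^1.7` used only for reporting.

## 4. Protocol engine

1. **Recruitment maneuver**: PCV, driving pressure 20, RR 10, PEEP
   staircase 5→30 cmH₂O in 5-cmH₂O/10-breath steps, final stage (peak
   50 cmH₂O) 20 breaths.
2. **Decremental titration**: VCV 6 ml/kg, RR 20, from PEEP 30 in
   2-cmH₂O/2-min steps; per-step `Crs` is the mean of the last five
   breaths; the trial stops two steps after the running maximum stops
   improving (ties keep the higher PEEP); open-lung PEEP = best + 2 cmH₂O,
   applied after a second recruitment maneuver.  Reaching the 4-cmH₂O
   floor with compliance still improving raises `TitrationError`.
3. **Closed loop** (4 h, 30-s ticks, three representative breaths per
   tick, analytic CO₂ update between ticks):
   - every 5 min, tidal volume moves ±1 ml/kg — Pplat arm: down when
     `Pplat > 30.5`, up when `Pplat ≤ 29` (the 0.5-cmH₂O deadband plus an
     anti-oscillation guard prevent a limit cycle when the achievable
     plateau is 30 ± the 1-ml/kg quantization); SI arm: down when
     `b > 1.05`, up when `b < 0.95`; floor 3 ml/kg;
   - every 1 min, pH rescue: `pH ≤ 7.15` and `RR < 35` → RR + 1 bpm;
     at the 35-bpm cap the 5-min review instead **raises** VT 1 ml/kg
     regardless of the arm rule;
   - hourly blood-gas review: when PaCO₂ leaves [35, 65] mmHg,
     `RR ← clamp(round(RR·PaCO2/55), 6, 35)`.  A 1-bpm hourly step was
     tried and rejected — it cannot track the CO₂ load on this time scale
     and strands PaCO₂ above 65 in both arms; the proportional retarget
     reproduces the observed controller behavior while the minute-cadence
     rescue ladder keeps its literal 1-bpm steps.

Snapshots are logged at 0, 60, 120, 180 and 240 min.

## 5. CT phantom

Aeration compartments by Hounsfield units, boundaries owned by the more
aerated class: overinflated [−1000, −900], normal (−900, −500], poor
(−500, −100], nonaerated (−100, +100]; outside [−1000, +100] is non-lung.
The phantom is four 64×64 anatomical levels split into ventral/dorsal
regions.  Closed units map to nonaerated voxels preferentially in the
dorsal region (rank = 0.85·depth + 0.15·jitter).  Open-voxel gas fraction
is `0.62 + 0.12·V_eff/(V_eff+0.5) + 0.25·σ((V_eff−0.45)/0.045)` capped at
0.98 — the logistic knee makes genuine overdistension (not mere
end-inspiration) cross the −900 HU boundary.  `HU = −1000·gas + N(0, 18)`.
Reports flag any compartment at ≥ 10% of regional lung voxels; the normal
compartment is never flagged.

## 6. Numerical and reproducibility choices

- Sample rate 100 Hz; explicit Euler for expiration (stable at these time
  constants); monotone bisection for the static equilibrium volume (the
  recoil is piecewise-polynomial and monotone).
- All stochastic draws (unit thresholds, phantom jitter, optional sensor
  noise) come from seeded `numpy` generators; identical config + seed gives
  byte-identical trace files.
- Trace CSV writes floats with `repr`, so round-trips are exact.

## 7. Limitations

- Single well-mixed CO₂ compartment; no metabolic compensation, no
  oxygenation model beyond a descriptive P/F surrogate.
- Units are identical except for thresholds; no regional resistances,
  pendelluft or viscoelasticity.
- The phantom maps global open-fraction and distension onto a stylized
  geometry; it is a counting/reporting testbed, not an image model.
- Controller cadences are idealized (instant measurements, no sensor
  drift); breath timing within a tick is representative, not continuous.
- The calibration reproduces component-compliance drops and titration
  behavior at desk scale; absolute hemodynamics, cytokines and histology
  are out of scope.
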