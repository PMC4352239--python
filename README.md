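# ventsi

A desk-scale simulator of **stress-index-guided mechanical ventilation** in a
virtual subject with surfactant-depletion ("lavage-type") lung injury and
intra-abdominal hypertension (IAH).

## The problem

In injured lungs, tidal ventilation can harm by two distinct mechanisms:
**overdistension** (too much volume stretches open units) and **cyclic tidal
recruitment** (collapsed units snap open and closed every breath).  During
constant-flow inspiration, volume rises linearly with time, so the shape of
the pressure–time curve reveals which regime the breath operates in.  The
**stress index (SI)** is the exponent `b` of the power fit

```
P(t) = a · t^b + c
```

over the constant-flow window: `b < 0.95` indicates tidal recruitment,
`b > 1.05` overdistension, and `0.95 ≤ b ≤ 1.05` a mechanically neutral
breath.  IAH complicates the picture: a stiff chest wall raises pleural
pressure, so airway pressures overestimate lung stress and a
transpulmonary-pressure-based SI is preferred.

`ventsi` packages, end to end:

- a **virtual patient**: 500 parallel lung units with hysteretic
  opening/closing pressures, nonlinear lung recoil with an injury-activated
  upper inflection, chest-wall stiffening and pleural-pressure coupling to
  intra-abdominal pressure, volume- and pressure-controlled breaths with
  end-inspiratory/end-expiratory occlusions;
- **waveform analysis**: constant-flow window extraction, the SI power fit
  (with a brute-force-verifiable least-squares core), static compliances
  (respiratory system, lung, chest wall), transpulmonary pressures, and
  auto-PEEP detection;
- **gas exchange**: alveolar-ventilation CO₂ kinetics with an exact
  exponential store update and Henderson–Hasselbalch pH;
- a **protocol engine**: staircase recruitment maneuver, decremental PEEP
  titration to the best-compliance step (open-lung PEEP = best + 2 cmH₂O),
  and a 4-hour closed loop that titrates tidal volume either to a plateau
  pressure of 30 cmH₂O or into the SI band, with a pH-rescue respiratory-rate
  ladder capped at 35 bpm;
- a **CT phantom**: Hounsfield-unit aeration compartments
  (overinflated / normal / poor / nonaerated) with gravity-dependent
  (dorsal) collapse and a 10% clinical-significance flag rule;
- **I/O and CLI**: YAML run configuration, exact-round-trip CSV traces, and
  the verbs `simulate`, `analyze`, `titrate`, `run`, `ct-report`.

## Worked example

```python
from ventsi import default_study_patient, run_protocol

patient = default_study_patient(seed=1)   # injured + IAH, 32 kg
titration, trace = run_protocol(patient, "si_target", seed=1)

print(titration.best_crs_peep, titration.ol_peep)
print(trace.snapshots[["T", "vt_ml_kg", "rr", "si", "pplat", "paco2", "ph"]])
```

On the frozen default subject this prints a best-compliance PEEP of
16 cmH₂O (open-lung PEEP 18) and hourly snapshots ending at

```
T4: VT 6.0 ml/kg, RR 26, SI 1.03, Pplat 32.5 cmH2O, PaCO2 57.7 mmHg, pH 7.24
```

The plateau-pressure-guided arm on the identical subject instead settles at
VT 5 ml/kg, RR 35 (rescue-driven), Pplat 29.7 cmH₂O, PaCO₂ 59.4 mmHg — the
emergent comparison (SI guidance sustains a higher tidal volume with lower
PaCO₂ under IAH, without overdistension) is asserted in the test suite.

Command-line equivalent:

```bash
ventsi run --arm si --seed 1 --out trace.csv
ventsi titrate --seed 1
ventsi simulate --breaths 5 --seed 1 --out wf.csv && ventsi analyze wf.csv
ventsi ct-report --seed 1
```

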