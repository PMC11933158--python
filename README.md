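# pisaflow

Quantification of mitral regurgitation by the **flow-convergence (PISA)
method**, exercised on synthetic velocity fields with known flow rates —
so every systematic error of the clinical estimator can be measured
against exact ground truth instead of lab data.

## The problem

Mitral regurgitation (MR) — retrograde systolic flow from the left
ventricle into the left atrium — is graded on echocardiography with the
flow-convergence method.  Color Doppler shows the aliasing isovelocity
contour upstream of the regurgitant orifice; assuming the converging
flow is an ideal hemispherical sink, the clinician reads the PISA
radius r at the chosen aliasing velocity V_a and chains

    RFlow = 2 π r² · V_a            regurgitant flow        [ml/s]
    EROa  = RFlow / V_max           effective orifice area  [cm²]
    RVol  = EROa · VTI              regurgitant volume      [ml]

where V_max is the peak jet velocity and VTI the velocity–time integral
of the jet over systole.  The hemisphere assumption fails for finite and
non-circular orifices, which biases RFlow — increasingly so at higher
aliasing velocities.  This package implements the whole chain plus the
machinery to quantify that bias:

- **geometry** — parametric orifice phantoms (circle, slit/pointed oval,
  drop) with closed-form areas and boundary polygons;
- **synthetic_flow** — convergence-zone potential-flow models (half-space
  point sink, exact circular-aperture profile, sink-sheet panel model
  for arbitrary orifice polygons, image-sink chamber confinement) and
  pulsatile jets (starting-vortex waveform, saddle-backed exit profiles,
  PIV-like sampling with frame ensembles and noise);
- **pisa_estimator** — beam projection, aliasing-radius extraction along
  the scan ray, and the RFlow/EROa/RVol chain;
- **piv_reference** — ground-truth RVol by streamwise-flux integration
  over exit-plane stations and systole, with bootstrap 2σ uncertainty;
- **sensitivity** — RFlow-error-vs-V_a curves, optimal aliasing velocity
  (zero crossing), ±20% admissible bands, size/shape sweeps.  On the
  exact aperture model the error is the closed form
  `rel_error(V_a) = −2π a² V_a / Q`;
- **diagnostics** — Q-criterion vortex maps, saddle-profile metrics;
- **grading_report** — ASE severity grading and the orchestrated
  PISA-vs-reference phantom study.

## Worked example

```python
import numpy as np
from pisaflow import (make_orifice, point_sink_field, FieldSeries, BeamSpec,
                      estimate_full, error_curve, SinkFlowSpec)
from pisaflow.sensitivity import admissible_band

# ideal convergence zone at the reference flow rate
Q = 244.9  # ml/s
x = np.arange(-3.6, -0.0999, 0.025)   # cm, 0.25 mm spacing
y = np.arange(-0.3, 0.3001, 0.025)
field = point_sink_field(Q, x, y)
series = FieldSeries(np.array([0.0]), [field])
m = estimate_full(series, Va=20.0, beam=BeamSpec(direction=(-1.0, 0.0)),
                  window=(0.0, 300.0))
print(f"PISA radius r = {m.r:.3f} cm")
print(f"RFlow = {m.RFlow:.1f} ml/s (true {Q} ml/s)")

# how the aliasing-velocity choice biases the estimate for a 12.2 mm orifice
circle_L = make_orifice("circle", 12.2, label="circle-L")
curve = error_curve(SinkFlowSpec(circle_L, Q, model="aperture_exact"))
for va in (16.0, 31.2, 47.5):
    err = curve.rel_error[np.argmin(np.abs(curve.va - va))]
    print(f"Va = {va:4.1f} cm/s -> RFlow error {100*err:+.1f}%")
lo, hi = admissible_band(curve, tol=0.2)
print(f"+-20% admissible band: Va in [{lo:.1f}, {hi:.1f}] cm/s")
```

prints

```
PISA radius r = 1.396 cm
RFlow = 244.9 ml/s (true 244.9 ml/s)
Va = 16.0 cm/s -> RFlow error -15.3%
Va = 31.2 cm/s -> RFlow error -29.6%
Va = 47.5 cm/s -> RFlow error -44.9%
+-20% admissible band: Va in [5.0, 20.9] cm/s
```

On the ideal point sink the chain is exact (first two lines).  On the
finite 12.2 mm aperture the same chain underestimates the flow, and the
bias grows linearly with the aliasing velocity: at the 31–48 cm/s
settings commonly chosen in practice the deficit reaches 30–45%, while
keeping V_a below ~21 cm/s holds it within ±20%.  That is the mechanism
by which large regurgitant orifices get under-graded.

A full phantom study (nine orifices, pulsatile jets, PISA vs reference
RVol with grades and deviation-vs-area tables) is one call:

```python
from pisaflow import StudyConfig, run_study
result = run_study(StudyConfig())
result.write("study_out", plots=True)
```

or from the shell: `pisaflow run-study --outdir study_out --plots`.
Other subcommands: `estimate`, `reference-rvol`, `sweep`, `diagnose`.

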