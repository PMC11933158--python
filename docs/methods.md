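# Methods

This note records the models behind `pisaflow`, the defaults and why
they were chosen, the numerical decisions that matter, and what the
synthetic data do and do not emulate.

## Coordinate and unit conventions

The orifice lies in the wall plane x = 0.  The convergence region
(ventricular side) occupies x ≤ 0, the jet (atrial side) x ≥ 0; the
streamwise velocity u is positive in +x.  The PISA scan ray runs from
the orifice centroid along −x (optionally tilted).  Orifice dimensions
are in mm, all flow quantities in clinical units (cm, cm/s, ml/s, ml,
cm²); the conversion happens only in the `geometry` accessors.

## Orifice phantoms

Three planar shapes, each with height h (the diameter for a circle) and
width w:

- **circle** — area πh²/4, exact;
- **slit (pointed oval)** — a symmetric two-arc lens: two circular
  segments sharing the chord w, each with sagitta h/2, giving sharp
  tips at ±w/2.  Arc radius R = (w²/4 + h²/4)/h, segment area
  R²(θ − sin θ)/2 with θ = 2 asin(w/2R);
- **drop** — a disk of diameter h joined to its tangent wedge whose
  apex sits at axial distance w from the blunt end; area
  R²(π − φ) + R√(d² − R²) with R = h/2, d = w − R, φ = acos(R/d).

The slit and drop boundaries are surrogates: the physical phantoms were
laser-cut and characterized by a flatbed scanner, and no CAD curve is
available.  The surrogates reproduce the scanner-measured areas of the
nine-phantom catalog to within ~11% (best for the large sizes: the
circle-L model area differs by 0.17%, slit-L by 1.2%, drop-L by 4.4%;
small laser-cut phantoms deviate the most from ideal curves, with
drop-S at −10.9%).  Boundary polygons are counter-clockwise, centred on
the area centroid, and their shoelace area converges to the closed
forms as the vertex count grows — that consistency is what the tests
assert.

## Convergence-zone flow models

All convergence-side generators are steady potential flows with an
exactly known flow rate Q, so the PISA chain has closed-form oracles:

- **point sink** (half-space): speed Q/(2πR²) toward the origin.  The
  flow-convergence method is exact here by construction; the estimator
  test demands recovery of Q to 0.5% at every aliasing velocity, which
  isolates pure interpolation error.
- **circular aperture** (exact): axial velocity u(x) = Q/(2π(x² + a²)).
  This yields the package's central closed form for the aliasing-
  velocity bias: the extracted radius satisfies r² = Q/(2πV_a) − a², so
  rel_error(V_a) = −2π a² V_a / Q — a linear underestimation growing
  with V_a and orifice size.  It depends only on V_a·a²/Q
  (dimensional-similarity property).
- **sink sheet**: the orifice polygon triangulated into radial rings
  (≥ 512 panels by default), each panel a half-space point sink of
  strength proportional to its area.  Ring triangulation matters: a
  boundary fan would place all panel centroids on a single ring and
  distort the near field.  The uniform-strength sheet equals the
  uniform sink disk on the axis, u(s) = σ(1 − s/√(s² + R²)) with
  σ = Q/A, and approaches the exact aperture profile only beyond
  ~2.5 radii — the exact aperture solution has a non-uniform density.
  Flux through any enclosing hemisphere is Q to machine precision
  (strengths sum to Q and the wall is impermeable), which is the
  conservation check.
- **chamber confinement**: image sinks mirrored across walls at
  y = ±L (truncated at a configurable reflection order) raise far-field
  speeds relative to the free sink.  This reproduces the low-V_a
  over-estimation regime and creates an interior zero crossing of the
  error curve — the optimal aliasing velocity — which decreases with
  orifice diameter (≈ 32 / 20 / 15 cm/s for the 4.7 / 8.7 / 12.2 mm
  circles with L = 2 cm, order 3).

The aliasing contour is located by walking outward from the on-ray
velocity maximum to the first sample below V_a, with linear sub-cell
interpolation at the bracketing pair.  Starting at the maximum (rather
than the first sample) makes the rule robust to the artificial velocity
dip that discrete panels produce within one panel pitch of the wall;
contiguity makes isolated super-threshold noise islands farther out
irrelevant.  A V_a above the on-ray maximum or a contour beyond the
sampled domain raise typed errors rather than returning a radius —
both are physically meaningful outcomes (e.g. a 20 mm orifice at the
reference rate has an orifice-plane velocity of 39 cm/s, so no 40 cm/s
contour exists at all).

Beam geometry: the projected velocity is the component along the line
of sight, positive toward the probe.  A tilt reduces the measured axial
velocity by cos(tilt); its effect on the extracted radius depends on
the field (zero for the purely radial sink, a reduction for jets whose
axial speed decays radially) — which is why the peak-velocity deficit,
not the radius, is the robust signature of misalignment.

## Pulsatile jet and PIV-like sampling

The jet-speed waveform U(t) is zero outside a systole window
(default 180–480 ms of a 750 ms cycle, 80 bpm), rises to a local
maximum (the starting-vortex passage, default 80 cm/s at 210 ms), dips
by 10%, rises to the global maximum (default 100 cm/s at 245 ms) and
decays exponentially (τ = 50 ms).  All joins are C¹ — cosine blends
with zero end slopes, and the decay onset smoothed over 10 ms — so the
42-phase trapezoidal sampling of the flow rate converges cleanly.  The
exact time integral is evaluated per segment by adaptive quadrature to
machine precision; the programmed regurgitant volume of a jet is
A·∫U dt.

The exit profile is u(y, z, t) = U(t)·g(ρ̂) with
g = c·(1 + β ρ̂²)·taper(ρ̂), where ρ̂ is the normalized
boundary-distance coordinate (0 at the deepest interior point, 1 at the
rim), β the saddle amplitude (default 0.3: off-centre maxima near the
rim, u_center/u_max = 1/(1+β) for the untapered profile), and taper a
smoothstep to zero over a 1.5 mm shear-layer width at the rim.  The
taper plays two roles: it is the physically expected vena-contracta
shear layer, and it makes trapezoidal flux quadrature of the sampled
profile well posed (spatial quadrature bias −0.003% at the 0.53 mm PIV
pitch for circle-L, versus O(Δy) for a discontinuous slug profile).
The normalization c is fixed by fine quadrature so the instantaneous
flow is exactly U(t)·A.

PIV sampling resamples to a 0.5323 mm vector pitch, replicates each
phase into n frames (default 100) and adds i.i.d. Gaussian noise per
frame, vector and component, all behind one integer seed.

## Reference RVol and bootstrap

The reference integrator mimics planar-PIV evaluation: the streamwise
velocity at the exit station (one cell downstream) is integrated by the
trapezoid rule across y — either revolved about the axis for circular
jets (π∫u|y|dy) or combined across several light-sheet planes
traversed along z — and the resulting flow-rate curve is integrated
over systole, again trapezoidally, extending one phase sample beyond
each window edge so an onset between samples is not clipped.  Planes
span the orifice height rim-to-rim (where the tapered flux vanishes);
nine planes keep the plane-quadrature error below 1.5% for the smallest
phantom (the rig's five-to-seven layers carry 2–3% on these synthetic
profiles, whose structure is sharper than measured jets).

Uncertainty: frames are resampled with replacement within each phase, B
= 1000 replicates, and twice the replicate standard deviation is
reported as the 2σ half-width.  Flux and time integration are linear in
the velocity field, so per-frame fluxes are computed once and
resampled — mathematically identical to recomputing RVol per replicate.

A calibration caveat the tests expose deliberately: at acquisition
scale (42 phases, 100 frames, 0.53 mm pitch, 5% noise) the noise-driven
2σ half-width (~0.08 ml at 30 ml) is smaller than the deterministic
time-quadrature bias of the 42-phase trapezoid (−0.44%, i.e. −0.13 ml)
— the waveform's local/global peak structure at 210/245 ms is only two
phase samples wide.  A frame bootstrap quantifies sampling noise only;
it cannot cover discretization bias, so the 2σ interval around the
estimate systematically misses the exact programmed value at this
noise level even though the estimate itself is accurate to half a
percent.  The corresponding coverage test is left failing as a
documented property of the procedure at these conditions rather than
hidden by inflating the noise or the interval.

## Sensitivity analysis

For each configuration the on-ray speed profile is sampled once at
2·10⁻³ cm resolution and every V_a on the grid (default 5–60 cm/s,
step 1 — covering the 15–60 cm/s range recommended in the literature)
is located on it with the same crossing rule the gridded estimator
uses.  The optimal aliasing velocity is the zero crossing of the error
curve, linearly interpolated (with a flagged |error|-minimizing grid
point when the curve never changes sign, as for the unconfined models);
the admissible band is the maximal contiguous interval around it with
|error| ≤ 20%, edges refined by interpolation.  Shape sweeps use the
sink-sheet model; at equal area and V_a the error magnitudes order
slit ≥ drop ≥ circle — the drop behaves more like the circle, the
elongated slit departs the most from the hemisphere assumption.

## Diagnostics

The Q-criterion is computed from the in-plane 2×2 velocity-gradient
tensor (central differences, interior nodes only), as standard for
planar two-component PIV: Q = ½(‖Ω‖² − ‖S‖²), equal to ω² for
solid-body rotation and 0 for pure shear, Galilean-invariant, and
second-order accurate (verified against the analytic Q of a Lamb–Oseen
vortex).  Profile metrics quantify the saddle-backed exit profiles:
saddle index u_center/u_max, and the block-profile excess — the
fraction by which a uniform profile at V_max overstates the actual
flow, which is exactly the bias inherited by the EROa step.

## Grading and study orchestration

ASE boundaries: RVol < 30 / 30–44 / 45–59 / ≥ 60 ml and EROa < 0.20 /
0.20–0.29 / 0.30–0.39 / ≥ 0.40 cm² map to mild / moderate /
moderate-severe / severe (the recommendation table prints three header
labels over these four columns; the 45–59 vs ≥ 60 split is kept
explicit).  VCW < 0.3 / 0.3–0.7 / > 0.7 cm maps to three classes.
Every class boundary is closed on its lower edge; note this places
VCW = 0.7 cm in the severe class although the printed table reads
"0.3–0.7 moderate" — the one place the uniform closure rule overrides
the printed interval.

`run_study` generates a pulsatile jet per orifice, evaluates the
reference RVol (axisymmetric for circles, nine planes for slit/drop),
reads V_max and VTI from the jet, builds the configured steady
convergence model matched to the jet's peak flow, runs the PISA chain
at each configured V_a, grades both estimates and tabulates the signed
deviation (negative = PISA underestimates).  With the ideal point-sink
model the two pipelines agree within 2% for all nine phantoms (the
null-deviation control); with finite-orifice models the ml deficit
grows with orifice area.  Because one driving waveform is shared, Q
scales with area and the relative aperture error −2πa²V_a/Q = −2V_a/U
is size-independent; the growing relative errors seen clinically
additionally involve the aliasing-velocity choices of the operators,
which are outside this model.

## What the synthetic data do not emulate

Potential-flow convergence zones have no viscous boundary layer, no
unsteadiness, and the chamber is represented only through image sinks;
jets are frozen slabs near the exit with no entrainment, spreading,
Kelvin–Helmholtz roll-up or starting-vortex dynamics (the waveform
carries the starting vortex's temporal signature only); PIV noise is
i.i.d. Gaussian with no correlation-peak locking, out-of-plane loss or
outliers.  Passing tests therefore demonstrate the correctness and
internal consistency of the estimators and the closed-form structure of
the aliasing-velocity bias — not the full magnitude of errors on
measured data, which also include operator variability and probe
misalignment.
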