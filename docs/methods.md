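# Methods

This note records the models implemented in `phantomflow`, their
assumptions, the numerical choices behind them, and what the synthetic
generators do and do not emulate.

## Conventions and units

All computation is SI (m, s, kg, Pa). Pressures cross every text and
reporting interface in mmHg; the single conversion constant
(133.322387415 Pa/mmHg) lives in `phantomflow.units`. Velocity fields use a
fixed coordinate convention: x rightward, y upward, arrays indexed
`(frame, y, x)`. The pressure-drop sign convention is inlet minus outlet
everywhere: ΔP = P(a) − P(b), so a drop that drives forward flow is
positive.

The blood-mimicking fluid is ρ = 1037 kg/m³, μ = 4.1 mPa·s; the pump
waveform defaults are a 2.5 L/min plateau, 0.2 s pulse, 1.7 s period,
half-cosine ramps occupying 25 % of the pulse each.

## Pump waveform

The "sine-like" ramps are half-cosines: they join the zero and plateau
segments with continuous value and zero slope, and integrate in closed form
— stroke volume is Q_peak · t_pulse · (1 − ramp_fraction), 6.25 mL per
pulse at the defaults. The ramp fraction (0.25) is this package's choice;
only the qualitative ramp shape is externally prescribed.

## Analytic field oracles

Five closed-form flows supply ground truth for the pressure-drop estimator:

| kind | velocity | pressure | balance |
|---|---|---|---|
| uniform_unsteady | (u₀ + a t, 0) | −ρ a x | inviscid |
| stagnation | (k x, −k y) | p₀ − ½ρk²(x²+y²) | inviscid (Bernoulli) |
| solid_body_rotation | ω(−y, x) | p₀ + ½ρω²r² | inviscid (radial) |
| poiseuille_channel | (u_max(1−(y/h)²), 0) | −2μu_max x/h² | viscous |
| womersley_axial | Bessel profile at r=\|y\| | p₀ − G(t)·x | viscous, unsteady |

Each kind's velocity/pressure pair satisfies its governing balance; the
property suite verifies this symbol-free by finite differences (exact for
the polynomial kinds, truncation-limited for the Bessel one).

A consequence worth knowing: the three inviscid kinds have *linear*
velocity fields and *quadratic* pressures, so central and one-sided
differences, bilinear path sampling and trapezoid integration are all exact
on them — the estimator reproduces the closed-form ΔP to rounding. The
measurable convergence order of the chain is therefore demonstrated on the
Womersley field (see below).

## Scanner emulation

`emulate_bsi` reproduces the two artifacts of speckle-tracking velocimetry
that dominate downstream analysis: additive velocity noise and the
PRF-dependent rejection of low velocities (0.21 m/s and 0.13 m/s are the
thresholds of the swell and ventricle phantoms this package models).
Tracking quality is assigned binary values (good/bad, defaults 0.95/0.1)
because the scanner's TQ computation is proprietary and the downstream
estimator only consumes the 0.4 threshold. Rejection is applied to the
*noisy* speed, mirroring that a scanner rejects what it measures. The noise
is isotropic Gaussian per component with a free standard deviation (default
0.02 m/s): no speckle physics, beamforming or scan conversion is claimed,
and no vendor noise level is asserted. Passing tests therefore show the
pipeline's behaviour under masking and noise of realistic magnitude, not
fidelity to any particular scanner.

## Pressure-drop estimation

Pipeline: TQ mask → finite-difference derivatives → inviscid gradient →
path integral.

* Derivatives: second-order central where the full stencil is valid,
  first-order one-sided next to boundaries or masked samples, invalid where
  no stencil can be formed. The temporal scheme mirrors the spatial one.
* Path integral: the polyline from a to b is resampled at half the grid
  spacing, the gradient is sampled by validity-aware bilinear interpolation
  (weights of invalid corners dropped and renormalised; a sample with no
  valid corner is missing), and integrated by the trapezoid rule with gaps
  bridged linearly. Per-frame coverage is the fraction of path samples with
  valid support; frames below `min_coverage` (default 0.9) are flagged
  invalid, never extrapolated.
* The default path is a fixed straight polyline because the endpoints are
  held fixed across frames; an instantaneous-streamline mode (fixed-step
  RK4 on the unit tangent field) exists behind a switch, with stagnation
  seeds rejected and paths that exit valid data flagged truncated. Whether
  a real acquisition should re-trace the streamline per frame is left to
  the user; neither behaviour is claimed canonical.
* The viscous term is deliberately omitted (the estimator implements the
  inviscid balance); on the Womersley field the omission equals the
  analytic viscous term, and the test suite subtracts it explicitly and
  then measures the remaining discretization error, which converges at
  order ≈ 2 under frame refinement.

## Lumped phantom

The cavity is one compliant node: c dP_c/dt = q_in − q_out. The inlet
branch carries the prescribed pump flow through r_in and l_in, so the
inlet catheter reads p_in = P_c + r_in q_in + l_in dq_in/dt; the outlet
branch discharges through r_out and l_out into a reservoir at p_down, where
the outlet catheter sits. Limits built into the topology: with a stiff
cavity and no inertance, ΔP → (r_in + r_out) q_in; with zero inflow all
pressures settle to p_down.

The default constants (r_in = r_out = 2.5 MPa·s/m³, c = 10⁻⁸ m³/Pa,
l_in = 3·10⁵, l_out = 10⁵ Pa·s²/m³, p_down = 1 kPa) are **illustrative**,
chosen once so that peak drops are a few mmHg — the magnitude range of the
phantom experiments — and are not fitted to any physical phantom. The
negative ΔP phase arises from both inlet inertance and cavity discharge;
the two contributions are separable by configuration.

Integration uses LSODA (adaptive, automatic stiff/non-stiff switching) with
a 5 ms maximum step and rtol 10⁻⁹: the rigid-cavity limit makes the chamber
equation arbitrarily stiff, which rules out a purely explicit method.
Measurement noise is additive Gaussian on the reported pressures only,
reproducible from the seed.

The mass-balance residual (ΔV + V_out − V_in)/V_out uses Simpson quadrature
on the sampled flows by default, which keeps the quadrature below the
solver tolerance (residual ~10⁻⁸, against the 10⁻⁴ acceptance bound); a
trapezoid option exists, under which the residual scales visibly as the
sampling interval squared.

## Womersley benchmark

Analytic side: gradient G(t) = K₀ + Σ Re[Kₙ e^{iωₙt}] (sign convention
G = −dp/dz), Poiseuille steady part, Bessel-form harmonic profiles and flow
rates, and the phase lag of flow behind gradient rising from 0 to a quarter
period with α.

Numerical side: a 1-D radial θ-scheme (backward Euler by default,
Crank–Nicolson optional) on uniform nodes, l'Hôpital axis treatment
(4(u₁−u₀)/dr² at r = 0), Dirichlet wall, trapezoid flow quadrature. At each
step the spatially uniform gradient is solved so that the discrete flow
matches the prescribed Q(t), by superposing a unit-gradient response — a
flow-prescribed, pressure-recovered coupling.

Two numerical points matter:

1. **Consistent initialization.** The flow constraint makes the
   semi-discrete system an index-2 DAE: the initial profile must satisfy
   the *discrete* flow quadrature at t = 0. An inconsistent start (e.g. the
   analytic profile, whose trapezoid quadrature differs from Q(0) by
   O(dr²)) injects a gradient impulse of size O(dr²/dt) that grows as the
   step shrinks. The solver therefore projects any initial profile onto the
   constraint with a Poiseuille-shaped correction.
2. **Benchmark driving.** The exact pump curve of a physical rig is not
   available, so the benchmark drives the tube with the steady plus
   fundamental Fourier terms of the package's own pulse waveform, converted
   to gradient amplitudes through the analytic flow factor. At the default
   tube (R = 5 mm, L = 0.1 m, f = 1/1.7 Hz, α ≈ 4.83) and resolution
   (64 radial nodes, dt = 2.5 ms), the recovered pressure-drop amplitude
   matches the closed form to ≈ 0.13 %; the baseline vs half-resolution
   differences of cycle-maximum pressure and stroke volume are ≈ 0.2 %.
   Amplitudes are measured over the second simulated period.

## Gel models

Uniaxial incompressible Yeoh: I₁ = λ² + 2/λ (the standard isochoric
invariant for uniaxial extension, stated here because it is easy to get
wrong), T = 2(λ − λ⁻²)[c₁ + 2c₂(I₁−3) + 3c₃(I₁−3)²]. The shipped
coefficients are (7.3, 9.4, 0) kPa. Fitting factors out 2(λ − λ⁻²) and
solves the linear-in-coefficients least-squares problem: exact on noiseless
data, rank-checked (stretches at λ = 1 carry no information), with standard
errors from the usual OLS covariance when degrees of freedom allow.
Stretch/stress data are assumed to be first Piola–Kirchhoff; the printed
equation is followed as-is.

Kelvin–Voigt: σ = Eε + ηε̇ pointwise; τ = η/E (defaults give 0.01 s). Creep
under constant stress is also available as an ODE integration so the
closed-form response (σ₀/E)(1 − e^{−t/τ}) can serve as an independent
check. Strain rates for measured histories use the same central/one-sided
differencing as the velocity-field module.

## Pulse protocol and statistics

Segmentation anchors either on the waveform time base or on upward
threshold crossings with hysteresis (starts snapped to exact one-period
spacing to tolerate ±2 samples of crossing jitter). The representative
curve is the pointwise mean of pulses 4–6 (discard 3, use 3, both
configurable). Extrema are taken on the averaged curve — average first,
extract second — with ties broken to the earlier time. Timing shifts
maximise the normalised cross-correlation with parabolic peak refinement;
positive lag means the second curve lags the first.

Replicate comparison: one-way ANOVA across groups and Welch (unequal
variance) t-tests pairwise at two-sided α = 0.05. These specific tests are
this package's choice for the comparison structure (across depths; between
methods); no multiple-testing correction is applied by default, matching
per-comparison reporting practice, and single-replicate groups are excluded
from testing with an explicit note. Reported SDs are across replicates
(scans), not across pulses within a scan.

## Problem sizes

Defaults were chosen so the full test suite runs in seconds on one core:
scan grids of ~21×21 nodes and 5 frames for oracle tests, 64 radial nodes ×
2.5 ms for the tube benchmark, one to six 1.7 s pump cycles at 1–5 ms
sampling for the phantom. All resolutions are parameters; the convergence
tests document how accuracy scales when they are refined.

## Known limitations

* The inviscid estimator carries the viscous term as a systematic bias;
  it is quantified on the Womersley field, not hidden.
* The lumped phantom reproduces curve shape and protocol, not the mmHg
  values of any physical phantom; its constants are illustrative.
* The scanner emulation is velocity-level only (no speckle images), with
  binary TQ and Gaussian noise of unasserted magnitude.
* The tube solver is rigid-wall and axisymmetric; no compliant-wall or 3-D
  fluid–structure coupling is attempted.
* 2-D estimation cannot capture out-of-plane transport; paths are confined
  to the scan plane.
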