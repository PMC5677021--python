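# Methods

This note records the models behind `depforce`, the defaults and why they
were chosen, the numerical choices, and what the synthetic experiments do and
do not establish about a real instrument.

## Electro-quasistatic field model

**Problem.** One lateral period of an interdigitated strip-electrode array:
electrodes of width *w* = 40 μm separated by *g* = 10 μm gaps at *z* = 0,
buried under a *t* = 0.8 μm silicon dioxide layer (ε_r = 3.9), with water
(ε_r = 78.5) above. Electrodes are long parallel strips, so the field is
treated as invariant along their length and solved on the 2D (x, z)
cross-section. At 1 MHz in low-conductivity water the problem is
electro-quasistatic: ∇·(ε∇Φ) = 0.

**Boundary conditions.** The published descriptions of such chips rarely fix
these, so they are package choices: alternating electrodes at ±V/2
(symmetric drive — the standard way to bias an IDT pair), grounded Dirichlet
top boundary at the domain height (default 100 μm = one period, where the
field has decayed by e^(−2π) ≈ 2×10⁻³), periodic lateral boundaries over one
period, and zero normal flux on the exposed gap segments of the bottom plane
(no charge on the dielectric there).

**RMS convention.** All stored potentials are RMS-scaled: electrodes sit at
±v_pp/(4√2). Squared-field quantities (energies, forces) computed from Φ are
then time averages of the sinusoidal drive with no further factors. Drive
specifications quote peak-to-peak volts throughout.

**Discretization.** Uniform grid, default spacing 0.2 μm (electrode edges and
the oxide interface must fall on grid nodes; the constructor enforces
spacing ≤ gap/4). Finite-volume 5-point stencil with face permittivities —
vertical faces take the permittivity of the layer they cross, horizontal
faces at the oxide interface take the arithmetic mean — which enforces
dielectric flux continuity. The resulting sparse system is solved directly
(SuperLU); the unit-potential problem is solved once and scaled by the drive,
so linearity in v_pp holds to float rounding by construction. The maximum
dielectric-weighted flux divergence over interior nodes is checked against
10⁻⁶ × max|Φ| after every solve (direct solves land near machine precision,
~10⁻¹⁶).

**Validation oracles.** (1) A uniform-permittivity plate-capacitor fixture
run through the same assembly must return a potential linear in z. (2) An
independent analytic solution for bare coplanar strips — Fourier modes of the
z = 0 profile (electrodes at ±V, linear interpolation across gaps) extended
into the half space with exp(−2πmz/P) decay — agrees with the numeric solver
(oxide removed) to < 1% relative L2 above one gap height; the 5% documented
tolerance leaves room for the differing gap boundary treatment (Neumann vs
imposed linear profile).

**Derivatives.** Mixed partials up to order 4 by nested second-order central
differences (numpy gradients), with wrap padding in x so the periodic seam is
clean; z boundaries fall back to one-sided stencils and points within
`order × spacing` of them are refused. Polynomials up to the stencil order
are differentiated exactly, which the tests exploit. In 2D every component
with a y index is identically zero and is reported as such.

## Multipolar DEP force

Per-order energies use the order-n Clausius–Mossotti factor
K_n = n(2n+1)(ε̃_p−ε̃_m)/(nε̃_p+(n+1)ε̃_m) with ε̃ = ε_r − iσ/(ε₀ω). Choices:

- **Re(K_n)** enters the energy: the in-phase polarization response is what
  survives time averaging of a sinusoidal drive.
- **(2n+1)!! sits under r^(2n+1)**; with this placement the n = 1 term
  reproduces the classical time-averaged dipole energy
  −2π ε_m Re(CM) r³ |E_rms|² exactly (3!! = 3 against K₁ = 3·CM), which the
  tests verify to machine precision, and which fixes sign and normalization.
- **Truncation at n_max = 3** by default. The n = 0 term vanishes
  identically (K_n ∝ n) and for the 15 μm bead over the 40/10 μm chip the
  octupole already carries < 0.1% of the force; the convergence ratio
  |F_nmax|/|F_total| is reported with every evaluation and a non-decreasing
  per-order magnitude sequence raises a warning.
- **Point-multipole evaluation at the bead centre.** Finite-size and
  wall corrections are out of scope; for a bead whose radius is comparable to
  the field decay length this is the leading approximation, and the absolute
  calibration inherits its (order-unity, not order-ten) uncertainty.

Forces are F_n = −∇U_n by central differences of the energy maps, reported in
pN; the independent classical dipole map (CM factor and ∇|E|² directly, no
K_n machinery) is kept as a cross-check of the n = 1 restriction.

**Dielectric defaults.** DI water ε_r = 78.5, σ = 2×10⁻⁴ S/m; polystyrene
ε_r = 2.55 with σ = 10⁻³ S/m as a surface-conductance proxy for carboxylated
beads. At 1 MHz the dielectric contrast dominates and Re(K₁) < 0 (negative
DEP — beads are pushed to the field minima over the electrode centerlines)
for any plausible values of the conductivities.

**Calibration.** F = c·v_pp² is exact given field linearity. c is evaluated
at the bead rest position — over the electrode centerline, one radius above
the oxide — and reported as the magnitude of the vertical (rupturing) force
component. For the reference chip this gives c ≈ 1.08 pN/V_pp², i.e.
≈ 4.3 pN at 2 V_pp, consistent with operating the instrument at 4 pN/s by
ramping 0 → 2 V_pp in one second.

## Staircase ramps

A schedule with N updates holds voltage V_k = v_max√(k/N) (force-linear mode)
on [t_k, t_{k+1}), t_k = k·duration/N, with duration = c·v_max²/r. The
force-linear square-root spacing is the primary mode because the instrument's
staircase is meant to realize a linear *force* ramp; an equal-voltage mode is
retained for comparison (its force ramp bends as V², and the linearity report
quantifies how much). The supremum deviation of the staircase from the ideal
ramp r·t is exactly one force step F_max/N (RMS: F_max/(N√3)), both computed
in closed form per hold. Camera synchronization follows
capture rate = samples_per_cycle × drive frequency, default 2, so alternating
half-cycles are each imaged once.

## Bell-model rupture kinetics

The generative bond model is single-barrier Bell kinetics
k(F) = k₀·exp(F·x‡/k_BT) — chosen because it is the standard minimal model
for weak-bond dynamic force spectroscopy; the rate law enters through one
function, so alternative laws can be swapped in. Under a staircase the
hazard is constant per hold, so survival is exactly piecewise-exponential and
Monte Carlo sampling is done by inverse-CDF on the cumulative hazard — the
sampler and the closed form are the same law, which the KS tests confirm at
n = 10⁴.

**Reference bond: k₀ = 5×10⁻³ s⁻¹, x‡ = 2 nm, T = 298 K.** This is the
single parameter set used by the in-silico experiments. Rationale: a weak
non-covalent surface contact (hydrogen-bond / Van der Waals scale) with
rupture forces of a few to ~26 pN across loading rates 4×10⁻² – 3×10³ pN/s,
squarely in the pN-resolution regime DEP tweezers address, with the
Evans–Ritchie force still positive at the quasi-equilibrium end (which needs
k₀ < r_min·x‡/k_BT ≈ 2×10⁻² s⁻¹).

**Schedule sizing.** Sweeps size each schedule so that only a 10⁻⁴ fraction
of bonds survive the full ramp (F_max = ln(1 + L·β·r/k₀)/β with
L = ln 10⁴, β = x‡/k_BT), keeping censoring negligible without unbounded
ramps. Censored beads are always reported at the ceiling F_max, never
dropped.

**Digitization stability.** The recorded staircase force quantizes the
continuous ramp downward (mean −ΔF/2) while the weaker staircase hazard
delays rupture (mean +ΔF/2): the two first-order effects cancel, so
closed-form mean rupture forces for 400/200/100/20 steps agree to well under
2% (measured ~0.06% spread at 4 pN/s), and a single-step schedule shows the
largest deviation from the continuous-ramp mean — matching the behaviour the
instrument's stability study is designed to detect.

**Parameter recovery.** Characteristic force per rate is the KDE mode of the
sampled distribution (the Evans–Ritchie observable; the mean is reported
alongside). Because the Bell rupture-force density has a rate-independent
shape that merely shifts with ln(rate), the KDE's smoothing bias is constant
across rates and cancels in the regression slope, so x‡ = k_BT/slope is
recovered within a few percent from 6 rates × 10³ beads; k₀ from the
intercept carries the (small) constant mode bias. Degenerate inputs — a
characteristic force better explained as linear in the rate itself than in
its logarithm, the signature of force-insensitive kinetics — are flagged
rather than inverted.

## Event detection and synthetic imaging

Detection: baseline mean from the first 20 frames; rupture frame = first
frame whose absolute deviation exceeds 5 noise SDs for 3 consecutive frames.
The noise SD is estimated over the whole trace as the scaled median absolute
first difference (MAD/(0.6745√2)) — robust to the single step change and far
less variable than a 20-frame sample SD, which is what makes ±1-frame
accuracy at ≥ 99% attainable at step/noise = 8. Detection is
polarity-agnostic (a defocused bead may brighten or darken on lift-off) and,
being a z-score rule, invariant to global gain and offset. A noiseless trace
(zero SD estimate) falls back to a 10-gray-level absolute threshold. Frames
map to times by frame starts (t = frame/fps); the half-frame assignment
ambiguity this leaves is below one force step whenever fps ≥ 2 steps per
update, which the benchmark generator guarantees.

Ruptures inside the baseline window are undetectable by construction; the
reference conditions put < 1% of events there, and the closed-loop benchmark
(100 beads, default noise 5 gray levels on a 60-level step) recovers ≥ 95%
(typically 98–100%) of rupture forces within one force step.

The renderer emulates what matters to the pipeline and no more: flat-topped
smooth disks (1 px soft edge) on 50 μm-pitch centerlines, one global
pre→post level switch per bead at its true rupture frame, additive Gaussian
noise, deterministic per seed. It does **not** model defocus optics,
illumination gradients, shot noise, bead drift or touching beads — so passing
benchmarks demonstrate the logic of trace extraction, change-point detection
and force assignment, not robustness to real-microscope artefacts.

## Problem sizes

Defaults used by the test suite and the acceptance script: one 500×501-node
field solve at 0.2 μm (unit tests use 0.4 μm), 10⁴ beads for survival-law
checks, 6 rates × 10³ beads for parameter recovery, 100-bead image benchmarks
at 512×512 px. These sizes put every statistical check far above its noise
floor while keeping a full run in the tens of seconds on one CPU.

## Known limitations

- No 3D end effects, double-layer screening, or substrate modelling below
  the electrode plane; no electrothermal/electroosmotic flow, Brownian
  motion, or gravity/buoyancy shift of the rest position.
- Point-multipole treatment of a bead whose diameter (15 μm) is comparable
  to the field decay length; the absolute force calibration is therefore
  model-dependent at the tens-of-percent level even though all scaling laws
  are exact.
- Bell kinetics is an assumption, not an inference: real carboxyl–carboxyl
  contacts may show multiple barriers or rebinding, which the rate-law
  interface admits but nothing here fits.
- The detector assumes a quiet pre-rupture baseline; events inside the
  baseline window are lost, and no sub-pixel tracking or drift correction is
  attempted.
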