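# Methods

## The constant-torque model

The package's central object is the load curve of a rotary motor that
outputs a constant torque *T*ₐ (pN·nm) against viscous drag:

    f(γ) = Tₐ / 2π(γ + γₐ)

with *f* the rotation rate (Hz), γ the rotational drag coefficient of
the attached marker (pN·nm·s) and γₐ ≥ 0 a load-independent constant.
Two physical readings of γₐ are supported and are algebraically
indistinguishable in the load curve:

* **Model A** — γₐ is a real drag (the rotating filament's own friction).
  The motor angle obeys the overdamped Langevin equation
  dθ/dt = Tₐ/(γ+γₐ) + √(2k_BT/(γ+γₐ))·ξ(t).
* **Model B** — rotation is limited by a chemical step with zero-load
  rate *f*₀: f(γ) = (1/f₀ + 2πγ/Tₐ)⁻¹.  Substituting
  γₐ = Tₐ/2π·f₀ recovers the Model A curve exactly.

Both appear as generative simulators (`synthetic.simulate_angles`), as a
fitting model (`torque.fit_constant_torque`) and as the conversion pair
`model_b_gamma_a`/`model_b_f_noload`.

## Units

Lengths nm, time s, energy and torque pN·nm, drag pN·nm·s.  Viscosity
is stored in Pa·s and converted internally by 1 Pa·s = 10⁻⁶ pN·s·nm⁻²
(`units.eta_internal`; the round trip is exact).  Defaults: η = 1.35×10⁻³
Pa·s (the high-salt motility buffer at room temperature), k_BT = 4.1
pN·nm, camera interval 0.5 ms, pixel 98 nm.

## Simulators

**Model A** integrates by Euler–Maruyama on an internal grid of
(camera interval)/10, decimated to camera frames; since the drift is
state-independent, this integrator is exact in distribution for the
increments.  A drift of more than 0.5 rad per internal step raises a
stability error.  At k_BT = 0 the mean rate over any window equals
Tₐ/2π(γ+γₐ) to machine precision.

**Model B** is event-driven: step triggers are a Poisson process at
rate f₀·(360°/step size) (default step 60°, matching the hexameric
motor geometry); each step then relaxes viscously at angular speed
Tₐ/γ, i.e. takes γ·δ/Tₐ for a step of δ rad.  The resulting
piecewise-linear θ(t) is sampled at camera times by interpolation.  No
thermal diffusion term is added in Model B; its stochasticity is the
exponential dwell sequence.  The mean rate is exactly
(1/f₀ + 2πγ/Tₐ)⁻¹, verified against Model A to within 2% in the
acceptance suite (10 load values, ≥10⁵ steps each).

**Dual-spot rendering** implements the wedge-prism encoding: each frame
holds two pixel-integrated Gaussian spots; the pair mean encodes (x, y),
the pair separation along the prism axis encodes z as
separation = baseline + gain·z.  The axial gain of the real optical
path is instrument-specific, so it is a free calibration parameter
(default 0.5 nm separation per nm z, baseline 15 pixels).  Shot noise
is Poisson per pixel (so per-spot totals are Poisson with the
configured mean), plus Gaussian read noise on a constant camera offset.
Not modeled (out of scope): defocus/aberrated PSFs, hydrodynamic or
optical coupling between the two images, drift.

## Benchmark dataset (study conditions)

`build_benchmark_dataset` emulates the published sampling: 32 beads of
210 nm, 31 of 490 nm, 26 of 1.0 µm, and 12 tethered cells.  Defaults
chosen once, on the following grounds:

* Generator motor: Tₐ = 160 pN·nm, γₐ = 0.81 pN·nm·s — the headline
  wall-corrected fit values, so the corrected-variant fit is the
  self-consistent recovery target.
* Bead rotation radius ~ N(250, 50) nm clipped to [120, 450] nm: the
  published example orbit has R ≈ 250 nm; the spread across beads is
  unreported, so it is a configured (not fitted) quantity.
* Tethered cells: length uniform in 2–4 µm, cross-section radius
  250 nm (the cell width of 0.5 µm also sets the default bead–glass
  gap used by the wall correction).
* Rate noise: multiplicative Gaussian with CV 10%, matching the visual
  scatter of the published load plot; configurable.
* Bead wall gap 500 nm; rates are drawn from the closed-form model at
  the *wall-corrected* drag, so the "raw" fit variant reproduces the
  characteristic underestimate of torque (~120 pN·nm) seen when the
  correction is omitted.

Rates are drawn from the closed-form mean of the generative model; the
Langevin simulator is used where trajectories (not just rates) are
needed.  What passing recovery tests show: the fitting chain is
unbiased and its CIs calibrated *under these conditions* (independent
markers, correct drag model, multiplicative noise).  They cannot show
robustness to real-data pathologies such as surface interactions beyond
the wall correction, filament length variation between markers, or
directional switching.

## Hydrodynamic drag

All closed forms are evaluated in `hydrodynamics`:

* Sphere orbiting at radius R: γ = 8πηr³ + 6πηrR² (spin + translation).
* Near-wall correction for translation parallel to a plane wall:
  factor [1 − (9/16)x + (1/8)x³ − (45/256)x⁴ − (1/16)x⁵]⁻¹ with
  x = r/h and h = gap + r.  The series is truncated at x⁵ (the `order`
  option exposes lower truncations); with gap 0.5 µm this yields 1.39,
  1.22 and 1.11 for 1.0-, 0.49- and 0.21-µm beads — 1.4/1.2/1.1 at two
  significant figures.  The factor multiplies the full two-term sphere
  drag (the convention that reproduces the published corrected fit);
  tethered cells and filaments are never wall-corrected.
* Tethered cell: half the centre-pivot rod drag at twice the cell
  length, ½·(1/3)πηL³[ln(L/2r) − 0.66]⁻¹ with L = 2·(cell length) —
  the end-pivot equivalence.
* Helical filament: γ = 2πηb²L(2p² + 4π²b²)(p² + 4π²b²)⁻¹
  [ln(2p/r) − 0.5]⁻¹.

**Helix length convention.** The published structural parameters
(b = 0.22 µm, L = 4.3 µm, p = 2.1 µm, r = 7 nm) give 0.508 pN·nm·s
when L is read as contour length (the default here) and 0.608 pN·nm·s
when read as axial extent and converted to contour length by
√(p²+4π²b²)/p.  Both are below the published rounded figure of
0.7 pN·nm·s, whose convention is not stated; the discrepancy is
surfaced in the `DragEstimate.note` rather than absorbed.  The
scientific conclusion is unchanged: the filament drag is of the same
magnitude as the fitted γₐ ≈ 0.8 pN·nm·s, keeping Model A viable.

## Plane, circle, rate, QC

* **Plane search**: objective = coefficient of variation of in-plane
  radial distances about the Kåsa circle centre (the orbit "is
  circular" criterion made quantitative).  An SVD plane fit seeds a
  local grid search (±10° at 1°, then ±1° at 0.1°) followed by a
  Nelder–Mead polish; noiseless recovery is within 0.1°.  Normals are
  reported with θ ∈ [0°, 90°] (toward +z).
* **Circle**: algebraic Kåsa fit refined by geometric least squares;
  radii below 3× the localization noise floor set a low-signal flag.
* **Rate**: slope of the least-squares line of unwrapped phase vs time,
  divided by 2π; this uses every frame and yields an SE.  Because phase
  residuals of a diffusive trace are strongly autocorrelated, the
  reported SE is the larger of the regression SE and a batch-means SE
  over 8 blocks.  Sign convention: CCW-positive about the normal
  (camera viewpoint of an inverted microscope); time reversal flips the
  direction label, never the magnitude.
* **QC** (smooth-rotation selection): instantaneous speed binned by
  phase mod 60° (12 bins); modulation depth = (max − min)/mean of bin
  medians, threshold 0.5 (configurable — the published selection is
  qualitative); dwells are flagged when an interval between successive
  60° first-passages exceeds 5× the median interval.  Markers failing
  QC are excluded before torque fitting.

## Torque fitting

Nonlinear least squares of f = Tₐ/2π(γ+γₐ) in f-space, with the
reciprocal linearization 1/f = (2π/Tₐ)γ + 2πγₐ/Tₐ used only for
initialization (fitting in 1/f-space would inflate noise at low rates).
Weights 1/SE² are applied when every record carries a rate SE.  Both
parameters are bounded at zero; 95% CIs come from case-resampling
bootstrap (percentile method, default 1000 resamples, seeded — the
per-class samples are small, so asymptotic CIs were not used).  The
fit is scale-consistent: γ → cγ, f → f/c leaves Tₐ fixed and scales γₐ
by c.

The apparent-torque diagnostic emits 2πγf (declines with rate when
γₐ > 0) and 2π(γ+γₐ)f (constant under the model).  Constancy is tested
by regressing the γₐ-subtracted torque on the *model* rate at each
marker's load rather than on the measured rate: the same measurement
noise enters both the measured rate and the apparent torque, so a naive
regression has a positive errors-in-variables slope bias of order
T·CV² relative to the rate spread.

The bead-size summary fit is f = A·ϕ + B (linear in diameter ϕ).  The
published legend prints the form V = A/ϕ + B with A = −0.024 Hz·nm⁻¹,
which is dimensionally inconsistent with the plotted rates and with its
own intercept; the linear-in-diameter form reproduces the printed
predictions (≈22 Hz at 210 nm, ≈3 Hz at 1 µm) and is implemented as a
deliberate correction.  Note the three zero-load summaries in
circulation — extrapolated ~25 Hz, intercept B = 27 Hz, and
Tₐ/2πγₐ ≈ 31 Hz — disagree at the ~20% level; the package reports them
as alternative summaries and does not reconcile them.

## Energetics

Work per revolution W = 2π·Tₐ.  A hexameric ATPase facing an *n*-fold
symmetric rotor hydrolyzes 6n ATP per turn, input energy 6n·ΔG_ATP with
ΔG_ATP = 80 pN·nm in vivo (configurable).  Apparent efficiency
100·W/(6n·ΔG_ATP); at Tₐ = 160 this is 209% for n = 1 and 104.7% for
n = 2.  `feasible_n` returns the smallest n whose efficiency does not
exceed 100·(1+tol)% — default tolerance 10%, which admits n = 2 at
104.7% (measurement uncertainty on Tₐ); at zero tolerance it equals
⌈W/6ΔG_ATP⌉.  The direct-ratio efficiencies for n = 3 and 6 are 69.8%
and 34.9% (reporting 100·(2/n) instead would give 67% and 33%).

## Problem sizes and numerical choices

* Recovery/coverage checks run 100 benchmark seeds with 400 bootstrap
  resamples each; CI endpoints at 400 resamples are within the
  percentile-noise of the 1000-resample default.
* The tracking round-trip check uses 2000 frames at 10⁴ photons/spot
  (3D RMSE < 10 nm; the noiseless round trip closes to < 0.1 nm).
* Model A/B equivalence uses 10 loads over γ ∈ [0.1, 100] pN·nm·s with
  10⁵ steps per simulator per load (≈0.5% Monte-Carlo SE against a 2%
  band).
* Spot fitting: pixel-integrated (erf) Gaussian in a 7×7 window,
  window-edge median background, bounds keeping the centre inside the
  window; pairing accepts spot pairs within ±30% of the baseline
  separation along the prism axis.  Frames, not trajectories, carry QC
  flags; stacks with >20% unpairable frames are rejected.
* Degenerate inputs raise typed errors: collinear point sets (no
  plane), < 1 net turn (no rate), identical loads (unidentifiable fit),
  stubby cells (rod log term ≤ 0).

## Known limitations

* The localization and pairing algorithms are package choices; the
  original analysis pipeline for these data is not described at this
  level and may differ.
* The axial encoding is strictly linear here; real wedge-prism optics
  have a finite linear range.
* No multi-particle tracking, drift correction, step-dwell analysis of
  saw-tooth traces, or torque–speed knee modeling (the constant-torque
  model has none).
* Model B's dwell statistics are single-exponential; multi-step
  chemistry would narrow the dwell distribution without changing the
  mean-rate curve.
* The QC modulation depth is an extreme statistic of binned speed
  medians and is inflated by tracking noise on short recordings;
  expect reliable accept/reject decisions only with a few hundred
  frames per phase bin (≳1 s at 2 kHz for a ~25 Hz trace).
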