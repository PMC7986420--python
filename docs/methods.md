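# Methods

This note documents the models, numerical choices and known limitations of
`beamtune`.  It is written for users who need to judge what the package's
validation does — and does not — demonstrate about real beam lines.

## Forward models

### Lateral transport (`beamtune.optics`)

One transverse plane of a pencil beam is a Gaussian in (x, x′) phase space,
parametrized by width σ [mm], divergence θ [mrad], emittance ε [mm·mrad]
and a convergence sign.  Internally the second moments ⟨x²⟩, ⟨x x′⟩, ⟨x′²⟩
are propagated, because free drift and small-angle scattering are linear in
the moments:

* drift over d: ⟨x²⟩ ← ⟨x²⟩ + 2d⟨xx′⟩ + d²⟨x′²⟩ (with mrad→rad unit
  bridges), the determinant ⟨x²⟩⟨x′²⟩ − ⟨xx′⟩² = (ε/π)² being conserved
  exactly;
* air scattering: Fermi–Eyges moment increments of the Highland scattering
  power T = [13.6 MeV · z / (pv)]² · [1 + 0.038 ln(L/X₀)]² / X₀, taken
  constant over a geometry segment (protons lose ≲1 MeV over 1.5 m of air,
  so pv is effectively constant; the logarithmic thickness correction uses
  the full segment length so increments stay additive).  Over a traversed
  length L the increments are TL, TL²/2 and TL³/3 for ⟨x′²⟩, ⟨xx′⟩ and
  ⟨x²⟩.  X₀(air) = 304.2 m.

Spot FWHM = 2√(2 ln 2)·σ.  The unit test suite validates the transport
against an independent 2·10⁶-particle sampling oracle (Gaussian source plus
mid-slab Highland kicks) to better than 1 % over random feasible optics.

Deliberately not modeled: nozzle hardware (approximable by an extra
segment), nuclear halo, non-Gaussian spot tails, and energy loss in air
(the tuned mean energy is the effective energy at the source plane; the
synthetic generator uses the identical convention, so recovery experiments
are unaffected).

### Depth dose (`beamtune.depth_dose`)

The laterally integrated depth-dose curve is the Gaussian convolution of
the Bragg–Kleeman power-law pristine peak:

* range R [cm] = α E^p with α = 0.0022, p = 1.77 for protons in water
  (carbon uses effective constants scaled by A/Z² at equal E/u; its
  fragmentation tail is not modeled);
* pristine dose D₀(z) ∝ (R − z)^(1/p − 1) for z < R, zero beyond;
* total distal spread σ_R² = σ_strag² + (σ_E · dR/dE)², with range
  straggling σ_strag [cm] = 0.012 R^0.935 and the analytic Bragg–Kleeman
  slope dR/dE.

Two numerical choices matter:

1. **Bin-averaged pristine curve.**  D₀ has an integrable singularity at
   z = R.  Point-sampling it (with any capping rule) makes the discrete
   curve jump as R crosses sub-bin phases — enough to make the extracted
   R80 non-monotone in E at the 0.2 mm level, which cripples a simplex
   optimizer.  Each bin therefore stores the exact analytic average of D₀
   over the bin, from the closed-form antiderivative.  The discrete curve
   is then smooth in R and its integral exact.
2. **Edge-safe convolution.**  The Gaussian kernel (unit-sum, ±6σ_R
   support) is applied on a grid extended by the kernel support, so no mass
   is lost inside the requested window; curves are sampled at 0.1 mm
   (the standard commissioning bin) from 0 to R + 6σ_R and normalized to
   peak 1.

### Curve metrics (`beamtune.metrics`)

R80 is the distal crossing of 80 % of the curve maximum, linearly
interpolated between the bracketing samples; BPW50/BPW80 are widths between
the proximal and distal crossings; FWHM is the distance between the
half-maximum flank crossings.  Under bin noise the distal crossing takes
the outermost candidate and flank/proximal crossings the innermost
(nearest-peak) one.  The curve maximum is the maximum sample — matching the
convention of a brute-force linear-resampling extraction, against which the
implementation is tested to 10⁻³ mm.  An optional Gaussian-fit FWHM
estimator mirrors vendor spot-analysis tools.  Measured-curve smoothing is
available but off by default; all validation runs use raw curves.

## The tuning pipeline (`beamtune.tuning`)

All stages use the in-package Nelder–Mead simplex (reflection / expansion /
contraction / shrink = 1, 2, 0.5, 0.5; stable tie-breaking) with the
commissioning stop criteria: maximum simplex extent per coordinate < 10⁻⁴
or best objective < 10⁻⁵ mm², capped at 400 iterations.  Because a
collapsed simplex can stall on ill-conditioned landscapes, up to two
restarts re-span the simplex at the incumbent best (skipped once a restart
stops improving).  Initial simplex steps are 5 % of each starting
coordinate.

**Energy / energy spread.**  E and σ_E are only weakly coupled (through
straggling growth with range), so they are tuned alternately — E against
R80 at fixed σ_E, then σ_E against BPW80 at fixed E — for two rounds.  One
round leaves a ~0.1–0.3 mm R80 bias (the distal 80 % point shifts with
σ_R); the second removes it, making the result insensitive to the initial
spread guess.  Initial values invert the range–energy rule at the measured
R80 and take σ_E = 0.5 % of E.

**Optics.**  Per energy and plane, the objective is the sum of squared FWHM
differences over all measurement planes, plus λ·[(Δσ)² + (Δθ)² + (Δε)²]
against the preceding energy's final parameters (λ = 0.1; mixed units
summed as-is — the weight is calibrated for exactly this convention; since
ε is numerically the largest parameter, the regularizer effectively anchors
the ellipse area along the chain).  The lowest energy is unregularized.

Three identifiability facts shape the implementation; all were established
on synthetic data with known truth:

1. **σ²(z) is quadratic in z**, so five measured planes determine the three
   beam moments — but the curvature (divergence) component rests on
   sub-percent width differences over a ±200 mm lever arm and carries a
   standard error of order 50–80 % at 0.05 mm FWHM noise.  The ellipse area
   (emittance) is a *difference* of such terms and is essentially
   unidentified from single-plane widths.
2. **Search chart.**  The simplex searches (σ, θ, u), where u = ⟨xx′⟩/(σθ)
   is the signed correlation; ε = πσθ√(1−u²) and the convergence sign is
   the sign of u.  In the raw (σ, θ, ε, fixed-sign) coordinates a beam-waist
   crossing (u = 0) — a physically smooth event — is a hard boundary where
   simplexes jam; in the u-chart it is interior.  Box violations (u outside
   [−1, 1], non-positive σ or θ) are penalized continuously and
   proportionally to the violation, never by a flat wall.  The sign is held
   chain-consistent (majority of the pooled estimates), matching the
   one-sign-per-plane geometry the compiled model can represent.
3. **Anchoring.**  Initial values come from a pooled cross-energy moment
   estimate: per energy, the air-scattering contribution (known
   analytically) is subtracted from the measured squared widths, a parabola
   is fitted and drifted back to the source; across energies the size and
   correlation follow a linear trend while the noisy curvature is pooled by
   median.  Every energy starts its search there.  The lowest energy
   additionally confines its emittance to [0.2, 0.6] of the pooled waist
   bound πσθ during the fit: the chain's area scale is frozen by the
   regularizer to whatever the anchor picks, an unconstrained anchor
   drifts along the degenerate area direction to a noise-determined
   extreme, and an area anchored too *high* forces σθ inflation that
   measurably degrades every subsequent fit (area anchored low is absorbed
   by the correlation at no cost).  With the bracket, chain data terms sit
   at the measurement-noise floor across all tested seeds; without it,
   roughly a third of runs degrade thirty-fold.

Consequence for interpretation: tuned σ(z) predictions are accurate, but
the tuned emittance itself is a weakly determined compromise — consistent
with the observation that widely different emittances can produce nearly
identical beam-width behavior.

## Model generation and evaluation (`beamtune.model`)

Each of the eight parameters (E, σ_E, and σ/θ/ε per plane) is fitted by
least squares over nominal energy with candidate degrees 4–6; the lowest
degree whose RMS residual is within 5 % of the best candidate's is kept
(guarding against over-fitting).  Fits run on a scaled abscissa and are
stored as plain power-basis coefficients (lowest first) in a JSON schema
with explicit units; serialization is byte-stable.

Feasibility (positive parameters, ε ≤ πσθ) is validated at 50 probe
energies.  Tuned points may sit exactly on the waist bound, and because the
three curves are fitted independently the compiled ε(E) can overshoot the
bound between tuned energies by the order of the fit residual; overshoots
within 3 % are accepted and clamped onto the bound at evaluation, larger
violations raise an error naming the energies.

Evaluation simulates IDCs and spot sizes from the model at n (default 5)
evenly spaced measurement energies and aggregates signed differences
(simulation − measurement) per metric: average, min, max, RMS, absolute and
relative.  The dose-scaling factor is the mean of per-point
measured/simulated dose ratios (making the mean relative difference zero
after rescaling by construction); the ratio-of-means alternative is
available.

## Synthetic machines (`beamtune.synthetic`)

Presets mirror common clinical layouts: `synchrotron-20` / `synchrotron-5`
(62–253 MeV protons, 20 or 5 uniform energies, spot planes at 0, ±100,
±200 mm, source 1.3 m upstream, air throughout) and `cyclotron-27`
(100–226.7 MeV, 27 energies, planes at 0, ±100, ±150 mm).  Truth curves are
low-order polynomials in nominal energy with a small seeded jitter:
energy offsets of a few tenths of an MeV, σ_E ≈ 0.45–1.2 MeV, beam widths
of 4–7.5 mm, divergences of 1.4–2.4 mrad, emittance fractions of 0.45–0.55
of the waist bound, one converging and one diverging plane.  Noise defaults
emulate a careful measurement campaign: 0.5 % multiplicative dose noise per
0.1 mm IDC bin and 0.05 mm additive noise per FWHM record.  An optional
straggling-scale perturbation emulates a forward-model mismatch between
machine and tuning engine.

Because generator and tuner share the forward engines, zero-noise recovery
is an *exactness* check of the optimization machinery (the pipeline
recovers R80 to 0.003 mm and FWHM to <0.1 % — run unregularized, since
without noise there is no variance for the regularizer to trade against its
smoothing bias), while noisy recovery measures the method's statistical
efficiency.  Neither says anything about forward-model fidelity to a real
beam line — systematic Bragg-curve shape errors, detector response
(scintillator pixelation, volume averaging) and beam-halo effects are
outside the emulation.

## Validation summary

The test suite cross-checks every layer against independent oracles:
closed-form drift and focus identities; trapezoid quadrature of the
scattering power; a 2·10⁶-particle sampling oracle for lateral transport
(≤1 %); brute-force dense-resampling curve metrics (≤10⁻³ mm); scipy's
simplex as a reference minimizer; and hand-computed micro-examples of every
objective.  End-to-end, on the default 20-energy noisy machine, the
compiled model agrees with the synthetic measurements to ~0.01–0.03 mm mean
|ΔR80|, ~0.3 % mean relative |ΔFWHM| and ~0.3–0.9 % mean relative |ΔBPW80|
(5 evaluation energies; stable across seeds), and repeated optics tuning
with independent noise shows the λ = 0.1 regularization shrinking the
run-to-run spread of σ, θ and ε simultaneously — the motivation for
regularizing in the first place.
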