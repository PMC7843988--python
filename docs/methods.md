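# Methods

This note documents the models behind the package, the parameters that
matter, the design choices where the design was genuinely open, and what the
synthetic data do and do not establish about real measurements.

## Dielectric model

The solution permittivity is a single-Debye relaxation plus an ionic
conductivity term,

    ε′(c, ω) = ε∞ + Δε(c) / (1 + (ωτ(c))²)
    ε″(c, ω) = Δε(c)·ωτ(c) / (1 + (ωτ(c))²) + σ(c)/(ωε₀),

with Δε(c) = εs(c) − ε∞ and a linear concentration parametrization
εs(c) = εs0 − kε·c, τ(c) = τ0(1 + kτ·c), σ(c) = kσ·c (c in mg/ml). Defaults:

| parameter | water | NaCl | glucose | unit |
|---|---|---|---|---|
| εs0 | 78.4 | 78.4 | 78.4 | – |
| ε∞ | 5.2 | 5.2 | 5.2 | – |
| τ0 | 8.27 | 8.27 | 8.27 | ps |
| kε (static decrement) | 0 | 0.2 | 0.02 | per mg/ml |
| kσ (conductivity slope) | 0 | 0.2 | 0 | S·m⁻¹ per mg/ml |
| kτ (relaxation slope) | 0 | 0 | 0.003 | per mg/ml |

Water values are the standard 25 °C Debye parameters. The NaCl conductivity
slope equals the dilute-limit molar conductivity of NaCl (~126 S·cm²/mol ≈
0.216 S·m⁻¹ per mg/ml, rounded to 0.2); its static decrement is the
well-known dielectric decrement of saline. Glucose is a non-electrolyte: it
contributes no conductivity, mildly depresses εs, and slows the water
relaxation (kτ > 0), which at 12 GHz (ωτ ≈ 0.62, below the loss peak)
*raises* ε″. The net effect — loss increasing with concentration for both
solutes, far faster for NaCl — is the qualitative behavior the measurement
relies on. These are phenomenological stand-ins, not fitted to measured
permittivity spectra; anyone with measured ε′(c), ε″(c) should override the
slopes via the YAML `dielectric:` section.

The penetration depth implements the printed attenuation convention
P(l) = P₀e^(−2l/Dp) with Dp = c/(ω√(2ε′)√(√(1+(ε″/ε′)²)−1)) and ω = 2πf.
Note this pairing is a *field*-style convention: with the factor 2 in the
exponent, power falls by e² (not e) over one Dp. Both pieces are kept
exactly as written so they can be checked against closed forms; the
concentration analysis only ever uses the pair together, for which the
convention choice is a relabeling of Dp. ε″ = 0 returns an infinite depth
(`math.inf`) rather than raising, so lossless sanity cases compose.
Supported range: the model refuses concentrations where εs(c) would fall to
ε∞; no Cole–Cole/multi-Debye terms, no temperature dependence, no mixtures.

## Forward model (synthetic data generator)

The generator emulates the measurement chain, not the electromagnetic
boundary-value problem. The |H|² near-field is parametric:

* background: isotropic Gaussian (width 3 mm, amplitude 0.3) — the circular
  aperture pattern of the empty-tube scene;
* tube mode (filled tube only): Gaussian elongated along the tube axis
  (length scale 5 mm, transverse scale = tube outer radius 0.75 mm) with
  peak amplitude A = A₀ · g(f) · exp(−2·l/Dp(c, f)), where A₀ = 5,
  g is a Lorentzian of HWHM 1.5 GHz centered at 12 GHz (the waveguide/tube
  coupling resonance), and l defaults to the tube inner diameter (1 mm).
  Perpendicular E-field polarization multiplies A by 0.02 — the liquid then
  barely perturbs the field.

Concentration enters *only* through Dp(c): the calibration stage therefore
discovers its saturating exponential from the physics rather than having an
intensity–concentration curve injected. The amplitude ratio A₀ : background
= 5 : 0.3 makes the DI-water ROI signal ≈ 3× the background signal, the
regime the instrument operates in.

Film heating is q = k·|H|² (sheet coefficient k, default 1). The
plane-stress thermoelastic response uses a potential φ with ∇⁴φ = κ·q on a
periodic domain (κ the thermoelastic coupling, default 1), solved spectrally
after subtracting the mean of q (reported on the result; the periodic
problem has no response to a uniform source). Stresses are
σxx = −s·φ_yy, σyy = −s·φ_xx, σxy = s·φ_xy with one shared scale s. This
discretization is chosen because the second-derivative reconstruction is
then an *exact* discrete inverse — the identity
(∂²x − ∂²y)(σxx − σyy) + 4∂²xy σxy = s·κ·q holds mode by mode — giving the
round-trip and single-mode oracles something exact to pin. Realistic
(Dirichlet) boundaries are a non-goal; consequently stress fields wrap
around the domain edges, which is harmless for interior ROI statistics.

The polarimetric render uses the circular-input Mueller chain: retardance
δ = p·√((σxx−σyy)² + (2σxy)²) (p the photoelastic coefficient, default
0.05 per stress unit; defaults keep max δ ≈ 0.07 rad), fast-axis angle θ
with tan 2θ = 2σxy/(σxx−σyy), and analyzer intensity
I(A) = I_full/2 · (1 + sin δ · sin 2(A−θ)). The 45° frame carries the
normal-stress channel and the 0° frame the (negated) shear channel; the
renderer warns above δ = 0.3 rad where linearized extraction biases exceed
~1.5%. Baselines are rendered with zero stress from the same noise stream.

Noise: additive Gaussian CCD read noise per frame (σ = 0.01 of full scale),
i.i.d. pixels, averaged over n_frames = 3000; plus one multiplicative drift
scalar per replicate (σ = 0.5%) applied to the field amplitude — the
simplest model that produces replicate scatter for the ΔEmax statistic.
Because the average of n i.i.d. Gaussian frames is exactly Gaussian with
σ/√n, the averaged frame is sampled directly at that amplitude (the unit
draw is independent of n, so error-vs-n comparisons at a fixed seed are
exact). Every stochastic operation is a pure function of (inputs, seed);
dataset generators derive per-cell child seeds from one base seed and
record them in the manifest.

Not emulated: full-wave electromagnetics (no standing waves, no
tube-diameter resonances), heat diffusion/transients (the map is the
instantaneous source, not a temperature field), camera optics (PSF,
vignetting, fixed-pattern noise), and analyzer misalignment. Passing tests
therefore demonstrate the *analysis* is correct and self-consistent under
the stated physics — not that a real instrument meets the same numbers.

## Reconstruction

Derivatives are taken in physical mm using the grid pitch. Default stencil:
second-order central differences (second differences plus a composed
central cross stencil for ∂²/∂x∂y, exact on quadratics); a spectral stencil
is available and is the exact inverse of the periodic forward model.
One-sided boundary stencils are deliberately not used — a crop margin
(default 2 px, at least the stencil half-width) is removed instead, and the
cropped grid keeps its physical origin so ROI rectangles remain valid.
Since the operator amplifies high-frequency noise as k², noisy inputs get
Gaussian pre-smoothing (default σ = 1 px in the noisy pipeline, 0 for
noise-free data). The constant C is a single user-supplied scalar
(default 1): absolute heat units would require the indicator's photoelastic
constants, which the method does not calibrate. Outputs are in arbitrary
units throughout the calibration stage, which is invariant to that scale.

ROI statistics use half-open rectangles in mm selecting pixel centers;
grid/ROI conventions (0-based indices, x along the tube, y down) are stated
once in `teoim.grid` and enforced everywhere.

## Calibration and sensitivity

The fit I(c) = B + A·e^(−c/c₀) is unweighted least squares on
per-concentration means (matching how calibration points are plotted);
weighted and pooled-replicate variants are options. Initialization is fixed
(B₀ = min mean, A₀ = range, c₀₀ = half the span) so the fit is
deterministic; c₀ is bounded positive. ΔEmax ("maximum fluctuation from all
concentration measurements") is ambiguous between dispersion measures, so
two rules are implemented — max replicate sd (default) and max half-range —
and the chosen rule is recorded in the output. Cmin uses the analytic
derivative of the fitted model, not finite differences on data: the
statistic is defined on the fitted intensity function, and the analytic
form makes the monotonicity of Cmin(c) exact for every saturating fit. The
sweep difference curve breaks argmax ties toward the lowest frequency.

With all defaults the synthetic experiment yields c₀(NaCl) ≈ 70 mg/ml <
c₀(glucose), NaCl Cmin(0) ≈ 1 mg/ml (a few-fold smaller than glucose's),
intensity strictly decreasing in c for both solutes, and a sweep contrast
peaking at 12 GHz — the qualitative behaviors the analysis exists to
resolve. These numbers are recomputed, not quoted, by
`scripts/acceptance.py` and the test suite.

## Numerical choices and problem sizes

* Spectral solves/derivatives use `numpy.fft` with angular wavenumbers
  2π·fftfreq(n, pitch); the k = 0 biharmonic mode is set to zero (zero-mean
  solution), matching the minimum-norm dense solve.
* sin δ / R is evaluated via the normalized sinc to stay finite at R = 0.
* Frames are stored full-scale [0, 1] and written as 16-bit integers with
  round-to-nearest (quantization ≤ 2⁻¹⁶); reconstructed maps as float32
  TIFF, lossless.
* Test and acceptance problem sizes: 256×256 for round-trip checks, 128×128
  for the full experiment (11 concentrations × 5 replicates × 2 solutes plus
  a 9-point sweep, a few seconds end to end), 16×16 for the dense biharmonic
  oracle. These sizes already put discretization error far below the
  tolerances being checked; larger grids change nothing but runtime.

## Known limitations

* The near-field model is parametric; absolute intensities and the
  resonance shape are configuration, not prediction.
* Dielectric concentration slopes are literature-magnitude defaults, not
  fits to measured spectra; Cmin values transfer to a real instrument only
  after recalibrating them and the noise model.
* The method cannot attribute a response to a specific solute in a mixture
  (the responses add); no mixture model is provided.
* No regularized deconvolution: at high noise the second-derivative
  operator relies entirely on pre-smoothing and frame averaging.
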