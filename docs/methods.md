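# Methods

## Optical model

The sensing film is a cholesteric liquid crystal (CLC) anchored
homeotropically between crossed polarizers. We model it as a **single
uniaxial retarder** whose optic axis is the effective helical axis, tilted by
θ from the substrate normal. For propagation along the normal the effective
extraordinary index is n_o·n_e/√(n_e²cos²θ + n_o²sin²θ), giving the effective
birefringence Δn_eff(θ, λ), the retardation Γ = 2πΔn_eff d/λ for gap d, and
the ideal-retarder transmittance T = sin²(2φ)sin²(Γ/2) at azimuth φ.

Assumptions and consequences:

* The helix is reduced to one effective optic axis. A stacked Jones-matrix
  treatment of the cholesteric layer structure (and of selective Bragg
  reflection, pitch, focal-conic domain statistics) is out of scope; the
  single-retarder model reproduces the spectral-fitting behaviour and the
  tilt-induced blue shift with one free parameter, which is what the
  tilt-inversion procedure needs.
* φ defaults to 45°, the maximal-contrast orientation. Real textures average
  over domains with varying azimuth; since peak-normalized spectra are used
  for fitting, the azimuth factor cancels there.
* Scattering is **not** modelled spectrally. Haze and transmittance loss
  enter only as separate readout channels in `quantitation`; color
  (interference) and haze (scattering) are treated as independent channels.

Material dispersion uses Cauchy laws n(λ) = A + B/λ² + C/λ⁴ (λ in µm). The
default material is 8CB-like with n_o ≈ 1.524 and n_e ≈ 1.671 at 589 nm
(Δn ≈ 0.147). These are configuration defaults representative of a
cyanobiphenyl host, not fitted constants; quantitative work on another
mixture should supply its own coefficients.

### Principal interference peak

For the ideal retarder every interference order peaks at exactly T = 1, so a
raw grid argmax between near-equal maxima is decided by ~1e-4 sampling noise.
`principal_peak_nm` therefore defines the principal maximum as the
**longest-wavelength interior local maximum** — the lowest interference order
inside the window — refined by a local quadratic fit, falling back to the
grid argmax when the window contains no interior maximum. With the default
material at a 15 µm gap this gives 621 nm at θ = 43° and 495 nm at θ = 48°: a
126 nm blue shift for the ~5° tilt increase caused by analyte binding.

### Tilt inversion

`fit_tilt` minimizes the sum of squared differences between peak-normalized
simulated and observed spectra (400–700 nm at 1 nm, matching a typical
visible transmission measurement) over θ. The optimizer is a deterministic
coarse grid (0.25° steps over the bounds) followed by bounded scalar
minimization inside the bracketing interval; grid ties break toward the
smaller tilt, and `converged=False` flags a minimum sitting on a bound.
Peak-normalized spectra alias across interference orders, so with very wide
or truth-excluding bounds the in-bounds optimum can be a lower-order local
minimum rather than the bound nearest the truth; the returned fit is always
the in-bounds minimizer. Under 1 % multiplicative noise the six reference
conditions (43/48° at 15 µm, 45/49° at 10 µm, 46/50° at 5.5 µm) are recovered
within ±0.5° in ≥ 95 % of seeded replicates.

## Colorimetry

Tristimulus integration uses the CIE 1931 2° observer tabulated at 5 nm
(shipped as CSV, linearly interpolated) with k = 100/Σ S·ȳ so unit
transmittance gives Y = 100 under any illuminant. The default colorimetric
grid is 380–780 nm at 5 nm. The microscope lamp of the emulated measurements
is unknown, so the illuminant is configurable (D65 default; E and the 2856 K
Planck illuminant A available); hue-class conclusions are checked under both
E and D65. Display rendering derives the XYZ→linear-sRGB matrix from the
IEC 61966-2-1 primaries at full precision and applies Bradford adaptation
from the illuminant's own white to D65, so the reference white maps to
(255, 255, 255) exactly; out-of-gamut channels are clamped and flagged
(no chromaticity-preserving compression — the flag preserves the
information). Exact reproduction of printed texture hues is not attempted:
illuminant and camera response are unknown, so predicted colors are read as
hue classes and contrasts.

## Quantitation

* `channel_relative_intensity`: 100·C/(R+G+B) with channel sums over the
  ROI. Default ROI is the full frame minus a 5 % border; explicit rectangles
  (half-open, 0-based) or boolean masks are accepted. The three channel
  statistics sum to 100 by construction.
* `haze_percent` rejects I_d > I_t as a physically impossible reading rather
  than clipping it.
* `fit_calibration` averages replicates per concentration, then fits OLS
  (via statsmodels) of the means on either log10(c) — the semi-log
  calibration over the working range — or linear c. The intercept's standard
  error (closed form, validated against a residual bootstrap) is the *s* in
  LOD = 3s/|m| and LOQ = 10s/|m|; LOQ/LOD = 10/3 identically. Replicate SDs
  are retained for plateau detection, not used as regression weights.
* `detect_linear_range`: the plateau onset is the first concentration whose
  mean increase over the previous one (signed by the series' overall trend)
  falls below k × pooled replicate SD (k = 1 default; exact-zero tolerance
  when noise-free). Excluded plateau points are reported, never silently
  dropped. A decrease against the trend larger than 3 pooled SDs raises a
  warning, not an error.
* `calibrate_assay` chains plateau exclusion → semi-log calibration →
  low-range linear-axis fit (default: the 4 lowest in-range concentrations)
  for LOD/LOQ, mirroring the usual assay-validation procedure. The number of
  low-range points is configurable because conventions differ between labs.

A note on LOD-versus-noise scaling: the low-range **linear-axis** fit is
misspecified when the underlying response is log-linear, giving its intercept
SE a model-misfit floor, so its LOD does not shrink to zero with the noise.
The noise-scaling property (LOD ∝ σ) holds — and is tested — on the
correctly specified semi-log fit, where OLS linearity makes s exactly
proportional to σ.

## Synthetic data

The generator produces the three measurement channels the analysis consumes.
Readout series follow y(c) = baseline + slope·log10(c/c_min), clipped to
[0, 100], with an optional hard saturation: `saturation_onset` is the *last*
concentration on the linear part, and strictly higher concentrations sit on
the plateau. This convention makes the generator's ground-truth plateau index
coincide exactly with `detect_linear_range`'s first-flat-step rule in the
noise-free limit. Noise is additive Gaussian, homoscedastic per readout
(σ in percentage points, default 1.0, 3 replicates) — a deliberate
simplification; real replicate scatter is likely heteroscedastic and
instrument-dependent, so passing recovery tests demonstrate correctness of
the analysis chain, not instrument-level realism.

Default magnitudes are the emulated study conditions: BSA series over
1e-12..1e-2 g/mL with the red-channel statistic 29 → 45 % saturating above
1e-5 g/mL, haze 10 → 40 %, parallel transmittance 70 → 30 % and total
transmittance 60 → 7 %; CA125 series over 1e-10..1e-5 g/mL with haze
10 → 40 % and the red channel 30 → 47 %; the serum variant reads the green
channel.

Textures are a uniform background with a signal region (centred disk or
coffee-ring annulus, the deposit left by an evaporating protein droplet)
alpha-blended at fraction f(c) = f_max·logistic(steepness·(log10 c_eff −
midpoint)) with c_eff = min(c, saturation_onset); the hard clip gives the
texture channel the same exactly-flat plateau semantics as the readout
series. BSA mode blends a red signal into a green background; serum mode
swaps to a green signal on a yellow-orange background. Pixel noise is
additive Gaussian before integer clipping (default σ = 4 intensity levels).
Texture colors are chosen for contrast, so the absolute scale of the channel
statistic differs from measured micrographs; tests assert monotonicity,
plateau location and channel ordering, not absolute percentages. Noisy
spectra multiply the forward model by (1 + ε), ε ~ N(0, σ²) i.i.d. per
wavelength, clipped at zero.

All generators are deterministic given (model, seed); named substreams
(`substream(seed, name)`) derive independent reproducible streams from one
run seed.

## Numerical choices

* Δn_eff endpoint identities (0 at θ = 0, n_e − n_o at θ = 90°) are enforced
  exactly; round-off at the 1e-16 level is clamped.
* Tilt fitting: 0.25° coarse grid, bounded refinement with xatol = 1e-4,
  ties to the smaller tilt.
* Peak refinement: three-point quadratic; degenerate (non-concave) fits keep
  the grid point.
* Spectra with an all-zero maximum cannot be normalized (degenerate-input
  error); the homeotropic dark state is reported as an all-zero absolute
  spectrum and a black swatch.
* Problem sizes in tests and the acceptance script (301-point spectra,
  100 replicates per tilt condition, 50 calibrations per noise level,
  256-pixel textures) were chosen to keep the whole suite in the
  tens-of-seconds range while leaving Monte-Carlo margins comfortable.

## Known limitations

* No physical link between tilt disorder and haze is modelled — the
  correlation is treated as an empirical property of the readouts, so the
  generator cannot be used to study the scattering mechanism itself.
* The single-retarder model ignores azimuthal domain averaging and the
  helical layer structure; it is adequate for peak positions and hue
  classes, not for absolute transmittance levels.
* Calibration statistics assume independent Gaussian errors and average
  replicates before regression; replicate-level weighting is not
  implemented.
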