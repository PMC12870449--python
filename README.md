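# clcsense

Modelling and quantitation toolkit for **cholesteric liquid-crystal (CLC)
biosensors** — label-free sensors in which biomolecules adsorbing at a
vertically anchored CLC film tilt its effective optic (helical) axis, changing
both the birefringent interference color seen between crossed polarizers and
the amount of scattered light. The package is aimed at researchers developing
or analyzing such sensors: it provides the forward optical model and its
inversion, color prediction of microscope textures, the multi-readout
quantitation chain (texture RGB statistics, haze, transmittance differences,
calibration with detection limits), and a synthetic-data generator so that
every stage can be exercised and tested without instrument data.

## The model in brief

A CLC cell of gap *d* whose effective optic axis is tilted by *θ* from the
substrate normal acts on normally incident light as a uniaxial retarder with

    Δn_eff(θ, λ) = n_o n_e / √(n_e² cos²θ + n_o² sin²θ) − n_o,
    Γ = 2π Δn_eff d / λ,
    T(λ) = sin²(2φ) · sin²(Γ/2),

where *φ* is the azimuth between the optic-axis projection and the polarizer
(45° for maximal contrast) and the indices follow Cauchy dispersion laws.
Increasing *θ* raises Δn_eff, blue-shifting the principal interference peak —
the origin of the sensor's signal–background color contrast. Spectra map to
colors through CIE 1931 tristimulus integration and sRGB rendering, and
`fit_tilt` inverts the model by least squares on peak-normalized spectra.

Quantitation readouts:

* haze (%) = 100 · I_d / I_t (diffuse over total transmitted light),
* channel relative intensity (%) = 100 · C / (R + G + B) over an image ROI
  (red channel in buffer, green channel in serum),
* ΔT (%) = 100 · (T(0) − T(c)) / T(0) for transmittance-based series,

each calibrated by OLS with **LOD = 3s/|m|** and **LOQ = 10s/|m|** (*s* = standard
error of the intercept, *m* = slope), after excluding the saturated plateau
found by `detect_linear_range`.

## Worked example

`python examples/simulate_and_color.py` prints:

```
tilt 43 deg — background (no analyte)
  principal interference peak: 621.2 nm
  chromaticity xy: (0.375, 0.255)
  display color rgb8: (255, 140, 221)  (gamut clipped: True)
tilt 48 deg — signal (analyte bound)
  principal interference peak: 495.0 nm
  chromaticity xy: (0.231, 0.341)
  display color rgb8: (27, 173, 166)  (gamut clipped: False)
signal-background rgb distance: 236.9
```

A 5° tilt increase at a 15 µm gap moves the principal interference peak from
621 nm to 495 nm, and the predicted texture hue changes by an rgb distance of
237 — a high-contrast, eye-readable color change. The other examples follow
the same pattern: `fit_tilt_from_spectrum.py` recovers a 48° tilt from a
1 %-noise spectrum to 0.002°, `calibration_and_lod.py` recovers the generating
haze slope (2.947 vs 3.000 %/decade, R² = 0.996) and reports LOD/LOQ for a
saturating red-channel series, `texture_image_analysis.py` quantifies a
synthetic texture stack and locates its plateau, and
`serum_mode_green_channel.py` demonstrates the green-channel serum variant.

There is also a thin CLI (`clcsense simulate | color | fit-tilt |
quantify-image | calibrate | haze | synth`) whose outputs embed a
provenance block (config hash, seed, package version).

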