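# lightdose

Diffusion-approximation light dosimetry for wearable optical/thermal probes.

Phototherapy dosing fails when it relies on population-average optical
parameters: tissues differ, sites differ, and the same tissue changes during
a session. `lightdose` implements the computation chain of a wearable
two-distance diffuse-reflectance probe that measures each tissue's own
effective attenuation coefficient and turns it, in real time, into a
relative internal light-dose map, a regional oxygen saturation estimate, and
a depth-resolved temperature prediction. It is written for researchers in
tissue optics and biophotonics who want the full pipeline — forward models,
inversions, a telemetry simulator standing in for the hardware, and a Monte
Carlo transport oracle — as a tested Python library.

## The models

**Attenuation inversion.** In a scattering-dominated semi-infinite medium
the steady-state diffuse reflectance far from the source follows

```
R(r) ∝ (1/r²) · exp(−μeff·r),       μeff = sqrt(3·μa·μs′)
```

so two detectors at r₁ = 4.2 mm and r₂ = 20.1 mm from the LED give

```
μeff = ln( R₁r₁² / (R₂r₂²) ) / (r₂ − r₁)
```

independent of source power, detector gain and the boundary factor.

**Relative fluence.** The internal fluence rate of the equivalent isotropic
point source, Φ(r,z) ∝ (z/R³)(1 + μeff·R)e^{−μeff·R} with R = √(r²+z²),
yields dose maps normalized at a shallow reference point (r=0, z=1 mm) that
depend only on μeff and geometry.

**Oximetry.** With OD = −log₁₀R, ∂OD/∂r = (μeff + 2/r)/ln10; the
geometry-corrected two-distance ΔOD ratio across 730/855 nm gives
κ = μa(λ₁)/μa(λ₂), and the oxy/deoxy-hemoglobin mixture model turns κ into
rSO₂.

**Bioheat.** The steady Pennes equation
k·T″ + μa·φ₀·e^{−μeff·z} + ρb·cb·wb·(T₀ − T) = 0 with T(0)=Ts, T(∞)=T₀ has
the analytic solution implemented in full; in the perfusion-dominated
regime it reduces to T(z) ≈ T₀ + (Ts − T₀)e^{−m·z} with m = 0.0876 mm⁻¹,
mapping a surface-temperature stream onto depth.

**Monte Carlo oracle.** A vectorized photon-packet random walk
(Henyey–Greenstein scattering, implicit capture, Russian roulette, matched
boundary) provides the brute-force reference the diffusion models are
validated against.

## Worked example

```
$ python examples/invert_attenuation.py
phantom truth      : 0.1163 mm^-1
repeat estimates   : [0.1165, 0.1163, 0.1162]
reported mean      : 0.116 mm^-1  (RSD 0.17%)
relative error     : 0.027%
```

Three simulated near/far reading pairs on a skin-like phantom with 0.3%
detector noise are inverted and averaged; the reported mean pins the
phantom's true μeff to well under a percent, which is why three repeats per
wavelength suffice on real skin. The other scripts in `examples/` walk
through fluence reconstruction, the occlusion rSO₂ episode, the bioheat
depth projection, and the Monte Carlo validation:

```
$ python examples/mc_validation.py
mu_eff (theory)    : 0.2057 mm^-1
mu_eff (MC fit)    : 0.2042 mm^-1  (0.7% off)
depth-profile log correlation MC vs analytic: 0.9991
```

A `lightdose` CLI wraps the same functions (`simulate`, `invert-mueff`,
`fluence-map`, `rso2`, `bioheat`, `mc-validate`, `monitor`, `report`).

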