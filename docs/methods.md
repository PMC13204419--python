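# Methods

This note records the models `lightdose` implements, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Forward reflectance and attenuation inversion

The medium is homogeneous and semi-infinite, with absorption μa (mm⁻¹) and
reduced scattering μs′ (mm⁻¹), μs′ ≫ μa. The implemented reflectance model
is the streamlined far-field form

    R(r) = (3 / 2πr²) · (1 + (2/3)A) · μa·μs′ · exp(−μeff·r),
    μeff = sqrt(3·μa·μs′)

Only ratios of R enter any downstream quantity, so the prefactor — including
the internal-reflection boundary factor A, default 1 (matched boundary) —
carries no physical weight; it sets the simulator's absolute flux scale and
nothing else. The two-distance inversion
μeff = ln(R₁r₁²/(R₂r₂²))/(r₂−r₁) is exact under this model (machine-precision
round trip), invariant to common detector gain, and degrades gracefully:
negative inversions from noisy streams are returned with a warning flag
rather than raised, so batch processing continues.

Probe geometry defaults to the as-built layout r₁ = 4.2 mm, r₂ = 20.1 mm,
with a round-number 4/20 mm bench preset. At skin-like optics
(μa = 0.01 mm⁻¹, μs′ = 1.41/1.23/1.13 mm⁻¹ at 730/810/855 nm) the transport
mean free path 1/(μa+μs′) is 0.704/0.806/0.877 mm, so the near detector sits
at 6.0/5.2/4.78 transport lengths — at the edge of the classical ≥5-MFP
validity criterion for the diffusion approximation. MFP multiples can be
reported rounded or truncated, because both conventions appear in practice.

**Known systematic of the two-distance formula.** Full diffusion theory
(the extrapolated-boundary dipole solution) multiplies the exponential decay
by a (μeff + 1/ρ) factor that has not died out at r ≤ 20 mm. Against that
solution — and against Monte Carlo, which matches it to well under 1% — the
streamlined two-distance inversion overestimates μeff by roughly 15% at this
geometry. The package treats this as a property of the method, not a bug:
the inversion is exact under its own model, all relative-dose quantities are
driven by the measured (effective) value, and the Monte Carlo module
provides the unbiased dipole-shape fit for anyone who needs the
theory-consistent coefficient.

## Relative internal fluence

The internal fluence rate of the buried isotropic source (depth z0 = 1/μs′),
after Taylor expansion valid for z0 ≪ r or z0 ≪ z:

    Φ(r,z) ≈ (P/4πD) · 2(z0 + 2AD) · (z/R³)(1 + μeff·R) e^{−μeff·R}

In the target/reference ratio every system constant (P, D, A, z0) cancels,
leaving a map that needs only μeff and coordinates. The reference is the
shallow on-axis point (0, 1 mm); the grid cell containing it is pinned to
exactly 1. Defaults: r ∈ [−10, 10] mm, z ∈ [0, 10] mm, 0.1 mm step.

Numerical choices: Φ(r, 0) ≡ 0 under this approximation, so "surface"
profiles are evaluated on a fixed shallow slice z_eps = 0.1 mm (the z factor
is constant along the slice, so the r-shape is preserved); the log₁₀ display
grid is floored at 1e−12 to keep the surface row plottable; points with
R < z0 trigger a validity warning, not an error, since relative maps are
routinely plotted into that region.

## Two-wavelength oximetry

From OD = −log₁₀R, the model gives ∂OD/∂r = (1/ln10)(μeff + 2/r). The
derivative is replaced by the two-distance difference and the geometric term
removed:

    κ = [ (ΔOD_λ1 − 2Δr/(r_ref·ln10)) / (ΔOD_λ2 − 2Δr/(r_ref·ln10)) ]²
      = μa(λ1)/μa(λ2)      when μs′(λ1) = μs′(λ2)

The correction distance r_ref defaults to the **logarithmic mean**
Δr/ln(r₂/r₁) ≈ 10.16 mm: under the r⁻²e^{−μeff r} model,
ΔOD = [μeff·Δr + 2·ln(r₂/r₁)]/ln10 exactly, and the log-mean is the unique
r_ref whose correction removes the geometric term completely — it *is* the
logarithmic-derivative midpoint. Geometric-mean (9.19 mm), midpoint and
near-distance conventions are available; they leave a wavelength-independent
residual in the corrected ΔOD that biases κ at the percent level and are
provided for comparison with instruments that use them.

Saturation solves εHbO₂(λ₁)S + εHb(λ₁)(1−S) = κ·[εHbO₂(λ₂)S + εHb(λ₂)(1−S)].
κ at the pure-HbO₂/pure-Hb extinction ratios returns exactly 1/0, and the
estimator is monotone between those limits. Estimates outside [0, 1] are
clipped and flagged per sample — noise near the admissible boundary is
expected in a monitor and must not abort a session. The shipped extinction
table (730/810/855 nm) carries compiled approximate literature values; every
quantitative test is a round-trip construction, so no result depends on the
table's absolute accuracy. Frames missing one of the 2 wavelengths × 2
detectors are skipped and logged.

Because the estimator assumes wavelength-independent scattering, the
occlusion simulator generates fluxes with a common μs′ (the mean of the pair,
1.27 mm⁻¹) by default — the condition under which the estimator is exact —
and offers a dispersive mode (1.41 vs 1.13 mm⁻¹) that exposes the resulting
κ bias (≈ μs′₁/μs′₂ ≈ 1.25) for sensitivity studies.

## Bioheat

Steady one-dimensional Pennes equation with Beer–Lambert optical source;
m² = ρb·cb·wb/k. The full analytic solution
T(z) = T₀ + (us + C)e^{−mz} − C·e^{−μeff z}, C = μa·φ₀/(k(μeff²−m²)),
us = Ts − T₀, satisfies a finite-difference residual below 1e−6 of the
source-term scale and converges pointwise to the simple profile as φ₀ → 0.
The resonant case μeff = m is rejected (the printed solution's exponentials
must be distinct). Defaults: m = 0.0876 mm⁻¹, T₀ = 36.5 °C,
k = 5×10⁻⁴ W·mm⁻¹·°C⁻¹ (0.5 W·m⁻¹·K⁻¹ soft tissue) with the perfusion
product set consistently; φ₀ defaults to 0, selecting the
perfusion-dominated regime (μeff ≫ m) where the simple profile applies.

Time series are treated **quasi-statically**: each surface sample is mapped
through the steady solution independently. This is deliberate — thermal
equilibration is fast relative to the 2-minute drive periods of interest —
and it makes depth amplitudes attenuate exactly as e^{−mz}. No transient
heat equation is solved.

The safety monitor fires a shutoff event at the first sample strictly above
the threshold (default 43 °C, a common hyperthermia damage reference; the
threshold is configurable), at most once per contiguous excursion, and keeps
the source off thereafter.

## Phantom simulator

The generators emulate the wearable's telemetry under the bench and on-body
protocols: 20-sample LED stability series at 10 s intervals with
multiplicative Gaussian noise at 0.2–0.3% relative SD and no drift;
paired near/far detector readings from the forward reflectance model with
0.3% multiplicative noise (detector counts sit far above the dark floor, so
no additive term by default); occlusion episodes with first-order
fall/recovery kinetics (τ_fall = 4 s, τ_rise = 3 s, contraction at T = 0,
release at T = 11 s — invented dynamics; only the dip/recover shape is
asserted anywhere); and 60 s temperature-rise replicates
ΔT(t) = ΔT_max(1 − e^{−t/τ}) with ΔT_max = 0.15 °C/mW × power, τ = 60 s
(visible curvature without saturation in the 60 s window) and additive
sensor noise of 0.1 °C (the thermal sensor's ±0.5 °C absolute accuracy
scaled by 0.2, since repeatability is much better than absolute accuracy).
The default phantom derives its absorption from the hemoglobin mixture at
70% saturation and 23 µM effective total hemoglobin, landing μeff near
0.14 mm⁻¹ at 730 nm — the low end of the range seen across individuals.

Every generator is a pure function of its arguments and seed (bitwise
reproducible). What the simulator does **not** emulate: layered skin
(epidermal melanin in particular), probe-pressure and contact artifacts,
ambient-light leakage, detector nonlinearity, and transport-layer effects.
Tests passing on these phantoms therefore demonstrate the correctness of
the computation chain under its own assumptions, not the accuracy of the
homogeneous model on real layered skin.

## Monte Carlo oracle

Photon packets launch as a pencil beam at the origin into the medium
(μs = μs′/(1−g), default g = 0.9; the anisotropy and matched refractive
boundary are conventional choices for skin, and all comparisons are
formulated to be insensitive to them at the stated tolerances). Steps are
Exp(μt)-distributed; at each collision a μa/μt weight fraction is deposited
(implicit capture) into cylindrical (r, z) voxels — fluence is deposited
weight / (μa · voxel volume) — and the direction is redrawn from the
Henyey–Greenstein distribution. Packets below weight 1e−4 play Russian
roulette (survival 0.1). Crossing z < 0 escapes through the matched boundary
and scores radially binned reflectance per unit area. A kill boundary at
30 mm (validated to sit beyond the scored region) terminates wanderers; its
weight is tracked, so launched = escaped + absorbed + terminated holds to
float precision. The walk is vectorized over packets with array compaction;
5×10⁵ packets take about a minute on one core.

Two agreement statistics are exposed. (1) `attenuation_fit`: a two-parameter
(amplitude, decay) least-squares fit of the log extrapolated-boundary dipole
reflectance to the MC histogram over r ∈ [5·MFP, 15 mm]; it recovers μeff to
about 1% at 10⁵ packets. (2) `depth_profile_correlation`: Pearson r of log
MC vs log analytic on-axis fluence over z ∈ [2, 10] mm (shape, not scale).
The *plain* ln(r²R) window slope is also provided but is systematically
~15% steeper than −μeff in this window — diffusion theory itself predicts
that (the (μeff+1/ρ) prefactor again), and the MC reproduces the predicted
biased slope to under 1%. Comparing the plain slope directly to −μeff is a
misuse of the statistic at these radii; the test suite asserts the unbiased
fit against μeff and the plain slope against its own theoretical value.

## Problem sizes

Default test/reproduction scales: 5×10⁵ MC packets for the headline
agreement numbers (5×10⁴ in the unit tests), 19-point μeff grids for
inversion round trips, 61-sample occlusion episodes at 0.5 s resolution,
4001-point finite-difference grids for the Pennes residual. These are the
package's chosen balance of statistical tightness against a desk-scale run;
all are parameters.

## Known limitations

Homogeneous semi-infinite medium only — no layers, no melanin compartment,
no heterogeneous perfusion; relative (not absolute) dosimetry — calibrated
source power and absolute fluence in J/cm² are out of scope; two
chromophores only; quasi-static thermal treatment; the two-distance μeff
carries the ~15% far-field-formula systematic discussed above. The intended
use is revealing relative trends in light and heat distribution per user and
per session, not absolute quantitative dosimetry.
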