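"""Synthetic tissue-phantom telemetry generators.

These generators stand in for the wearable hardware: they emit the same
telemetry records the device would, computed from the forward models on a
phantom with known optical/thermal parameters, so every estimation pipeline
can be exercised against ground truth. Detector noise is multiplicative
Gaussian (readings sit well above the dark floor), LED output is stable to
a relative standard deviation of a few tenths of a percent, and occlusion /
temperature-rise dynamics are simple first-order kinetics chosen to
reproduce the qualitative shapes seen on tissue.

Every generator is a pure function of (its arguments, seed): the same seed
reproduces the same records bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .oximetry import ChromophoreSpectra
from .telemetry import TelemetryRecord
from .tissue_optics import OpticalProperties, ProbeGeometry, DEFAULT_GEOMETRY, reflectance
from .bioheat import ThermalProperties

__all__ = [
    "PhantomSpec",
    "forearm_phantom",
    "occlusion_saturation",
    "generate_detector_readings",
    "led_stability_series",
    "occlusion_series",
    "temperature_rise_series",
]

#: Reduced scattering of forearm skin at the three LED wavelengths (mm⁻¹),
#: standard literature values at 725/800/850 nm.
SKIN_MU_S_PRIME = {730.0: 1.41, 810.0: 1.23, 855.0: 1.13}

#: Effective total hemoglobin (molar) giving baseline absorption near
#: 0.005 mm⁻¹ — i.e. phantom μeff in the 0.14 mm⁻¹ range typical of
#: lightly pigmented forearm skin.
DEFAULT_TOTAL_HB_MOLAR = 2.3e-5


@dataclass(frozen=True)
class PhantomSpec:
    """A homogeneous tissue phantom plus its measurement-noise model.

    ``optics`` maps wavelength (nm) to the phantom's optical properties;
    ``saturation`` is the baseline hemoglobin oxygen saturation used by the
    dynamic (occlusion) generator, with ``total_hb_molar`` setting the
    absorption scale of the oxy/deoxy mixture. ``noise_rsd`` is the
    multiplicative detector noise, in percent relative SD.
    """

    optics: dict[float, OpticalProperties]
    thermal: ThermalProperties = field(default_factory=ThermalProperties)
    saturation: float = 0.70
    total_hb_molar: float = DEFAULT_TOTAL_HB_MOLAR
    noise_rsd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError(f"saturation must be in [0,1], got {self.saturation}")
        if self.noise_rsd < 0:
            raise ValueError(f"noise_rsd must be >= 0, got {self.noise_rsd}")

    def optics_at(self, wavelength: float) -> OpticalProperties:
        for wl, props in self.optics.items():
            if math.isclose(wl, wavelength, abs_tol=0.5):
                return props
        raise KeyError(f"phantom has no optics at {wavelength} nm")

    def with_noise(self, noise_rsd: float) -> "PhantomSpec":
        return replace(self, noise_rsd=noise_rsd)


def forearm_phantom(
    seed: int = 0,
    saturation: float = 0.70,
    noise_rsd: float = 0.3,
    total_hb_molar: float = DEFAULT_TOTAL_HB_MOLAR,
    spectra: ChromophoreSpectra | None = None,
) -> PhantomSpec:
    """Default phantom emulating lightly pigmented forearm skin.

    Absorption at each wavelength comes from the hemoglobin mixture at the
    baseline saturation; reduced scattering uses the literature skin values.
    The resulting μeff sits near 0.14 mm⁻¹ at 730 nm, matching the low end
    of the range measured across individuals.
    """
    if spectra is None:
        spectra = ChromophoreSpectra.default_table()
    optics = {}
    for wl, musp in SKIN_MU_S_PRIME.items():
        mu_a = spectra.mixture_mu_a(wl, saturation, total_hb_molar)
        optics[wl] = OpticalProperties(mu_a=mu_a, mu_s_prime=musp)
    return PhantomSpec(
        optics=optics,
        saturation=saturation,
        total_hb_molar=total_hb_molar,
        noise_rsd=noise_rsd,
        seed=seed,
    )


def _noisy(rng: np.random.Generator, values: np.ndarray, rsd_percent: float) -> np.ndarray:
    if rsd_percent == 0:
        return values
    return values * (1.0 + rng.normal(0.0, rsd_percent / 100.0, size=values.shape))


def generate_detector_readings(
    phantom: PhantomSpec,
    geom: ProbeGeometry = DEFAULT_GEOMETRY,
    wavelength: float = 730.0,
    n: int = 20,
    dt: float = 10.0,
) -> list[TelemetryRecord]:
    """Paired near/far detector readings of a static phantom.

    Flux is the forward semi-infinite reflectance at each detector distance
    times independent multiplicative Gaussian noise at the phantom's RSD.
    """
    props = phantom.optics_at(wavelength)
    rng = np.random.default_rng(phantom.seed)
    base = np.array([reflectance(props, geom.r1), reflectance(props, geom.r2)])
    records: list[TelemetryRecord] = []
    for i in range(n):
        near, far = _noisy(rng, base, phantom.noise_rsd)
        t = i * dt
        records.append(
            TelemetryRecord(t, wavelength, "near", geom.r1, float(near))
        )
        records.append(
            TelemetryRecord(t, wavelength, "far", geom.r2, float(far))
        )
    return records


def led_stability_series(
    n: int = 20,
    interval: float = 10.0,
    rsd: float = 0.23,
    mean_flux: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stationary LED-output series: constant mean, multiplicative noise.

    Emulates the bench stability protocol (readings every 10 s, 20 samples,
    relative SD a few tenths of a percent, no drift). Returns a DataFrame
    with ``timestamp_s`` and ``flux`` columns.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    flux = _noisy(rng, np.full(n, mean_flux), rsd)
    return pd.DataFrame({"timestamp_s": np.arange(n) * interval, "flux": flux})


def occlusion_saturation(
    t,
    baseline: float,
    drop_to: float,
    t_contract: float = 0.0,
    t_release: float = 11.0,
    tau_fall: float = 4.0,
    tau_rise: float = 3.0,
):
    """Ground-truth saturation trajectory of a muscle occlusion episode.

    Baseline before ``t_contract``; first-order decay toward ``drop_to``
    during contraction; first-order recovery to baseline after
    ``t_release``. The kinetics are invented first-order dynamics — only the
    dip/recover shape is meaningful, not the time constants.
    """
    t = np.asarray(t, dtype=float)
    s = np.full(t.shape, baseline)
    falling = (t >= t_contract) & (t < t_release)
    s[falling] = drop_to + (baseline - drop_to) * np.exp(-(t[falling] - t_contract) / tau_fall)
    s_release = drop_to + (baseline - drop_to) * math.exp(-(t_release - t_contract) / tau_fall)
    rising = t >= t_release
    s[rising] = baseline - (baseline - s_release) * np.exp(-(t[rising] - t_release) / tau_rise)
    return float(s) if s.ndim == 0 else s


def occlusion_series(
    phantom: PhantomSpec,
    drop_to: float = 0.45,
    t_contract: float = 0.0,
    t_release: float = 11.0,
    duration: float = 30.0,
    dt: float = 0.5,
    t_start: float = -5.0,
    geom: ProbeGeometry = DEFAULT_GEOMETRY,
    wavelength_pair: tuple[float, float] = (730.0, 855.0),
    spectra: ChromophoreSpectra | None = None,
    dispersive_scattering: bool = False,
) -> list[TelemetryRecord]:
    """Telemetry stream of a muscle contraction/relaxation episode.

    Per time point, the saturation trajectory sets μa at each wavelength via
    the hemoglobin mixture, fluxes come from the forward reflectance model at
    both detector distances, and multiplicative noise is applied at the
    phantom's RSD. Four records per time point: two wavelengths x two
    detectors.

    The two-wavelength saturation estimator assumes μs′ is the same at both
    wavelengths, so by default the stream is generated with a common reduced
    scattering (the mean of the phantom's pair values) — the condition under
    which the estimator is exact. Set ``dispersive_scattering=True`` to keep
    each wavelength's own μs′ and expose the resulting estimator bias.
    """
    if drop_to > phantom.saturation:
        raise ValueError("drop_to must not exceed the baseline saturation")
    if spectra is None:
        spectra = ChromophoreSpectra.default_table()
    rng = np.random.default_rng(phantom.seed)
    times = np.arange(t_start, t_start + duration + dt / 2, dt)
    sats = occlusion_saturation(
        times, phantom.saturation, drop_to, t_contract, t_release
    )
    musp_common = float(
        np.mean([phantom.optics_at(wl).mu_s_prime for wl in wavelength_pair])
    )
    records: list[TelemetryRecord] = []
    for t, s in zip(times, sats):
        for wl in wavelength_pair:
            musp = phantom.optics_at(wl).mu_s_prime if dispersive_scattering else musp_common
            mu_a = spectra.mixture_mu_a(wl, s, phantom.total_hb_molar)
            props = OpticalProperties(mu_a=mu_a, mu_s_prime=musp)
            base = np.array([reflectance(props, geom.r1), reflectance(props, geom.r2)])
            near, far = _noisy(rng, base, phantom.noise_rsd)
            records.append(TelemetryRecord(float(t), wl, "near", geom.r1, float(near)))
            records.append(TelemetryRecord(float(t), wl, "far", geom.r2, float(far)))
    return records


def temperature_rise_series(
    power: float,
    duration: float = 60.0,
    dt: float = 5.0,
    reps: int = 10,
    tau: float = 60.0,
    rise_per_mw: float = 0.15,
    noise_sd: float = 0.5 * 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated surface temperature-rise curves under constant irradiation.

    The underlying mean rise is a saturating exponential
    ΔT(t) = ΔT_max·(1 − e^{−t/τ}) with ΔT_max = ``rise_per_mw``·power, so
    doubling the optical power doubles the asymptotic rise. Additive sensor
    noise defaults to the thermal sensor's ±0.5 °C accuracy scaled by 0.2
    (repeatability is much better than absolute accuracy); t = 0 reads
    exactly 0 by construction (rises are differences from the first frame).

    Returns a tidy DataFrame with columns ``rep``, ``timestamp_s``,
    ``delta_t_c``.
    """
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    dt_max = rise_per_mw * power
    mean_curve = dt_max * (1.0 - np.exp(-times / tau))
    rows = []
    for rep in range(reps):
        noise = rng.normal(0.0, noise_sd, size=times.shape)
        noise[0] = 0.0  # rise is measured relative to the first frame
        rise = mean_curve + noise
        rise[0] = 0.0
        for t, dT in zip(times, rise):
            rows.append({"rep": rep, "timestamp_s": float(t), "delta_t_c": float(dT)})
    return pd.DataFrame(rows)
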