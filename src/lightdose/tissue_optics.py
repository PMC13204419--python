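"""Semi-infinite diffusion forward model and two-distance attenuation inversion.

In a scattering-dominated medium (``mu_s' >> mu_a``) the steady-state diffuse
reflectance at a source-detector distance ``r`` well beyond the transport mean
free path follows

    R(r) ∝ (1 / r²) · exp(-μeff · r),        μeff = sqrt(3 · μa · μs′)

so the effective attenuation coefficient — the single parameter that sets the
exponential decay rate of light in tissue — can be recovered from the radiant
flux measured at two distances:

    μeff = ln( (R₁ r₁²) / (R₂ r₂²) ) / (r₂ − r₁)

This module houses the optical-property container, probe geometry presets, the
forward model, the inversion, and repeat-measurement summaries.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "ProbeGeometry",
    "RepeatSummary",
    "NegativeAttenuationWarning",
    "GEOMETRY_PRESETS",
    "DEFAULT_GEOMETRY",
    "effective_attenuation",
    "transport_mfp",
    "distance_in_mfp",
    "format_mfp_multiple",
    "reflectance",
    "invert_mu_eff",
    "summarize_repeats",
]


class NegativeAttenuationWarning(UserWarning):
    """Inverted attenuation came out negative (R1·r1² < R2·r2²)."""


@dataclass(frozen=True)
class OpticalProperties:
    """Optical parameters of a homogeneous tissue (or phantom).

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm⁻¹.
    mu_s_prime : float
        Reduced scattering coefficient ``μs′ = μs·(1−g)``, mm⁻¹.
    g : float
        Scattering anisotropy (Henyey–Greenstein mean cosine); only the
        Monte Carlo oracle uses it, the diffusion model depends on ``μs′``
        alone.
    boundary_A : float
        Internal-reflection boundary correction factor ``A``. Defaults to 1
        (matched refractive boundary); every downstream quantity implemented
        here is a ratio in which ``A`` cancels, so it only sets the
        simulator's absolute scale.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    boundary_A: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")
        if self.boundary_A <= 0:
            raise ValueError(f"boundary_A must be > 0, got {self.boundary_A}")

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3·μa·μs′), mm⁻¹."""
        return math.sqrt(3.0 * self.mu_a * self.mu_s_prime)

    @property
    def diffusion_coefficient(self) -> float:
        """Diffusion coefficient D = 1/(3(μa+μs′)), mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def z0(self) -> float:
        """Depth of the equivalent isotropic source, 1/μs′, mm."""
        return 1.0 / self.mu_s_prime

    @property
    def mu_s(self) -> float:
        """Unreduced scattering coefficient μs′/(1−g), mm⁻¹ (MC oracle)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient μa + μs, mm⁻¹ (MC oracle)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class ProbeGeometry:
    """Near/far source-detector distances of the two-distance probe, mm."""

    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not 0 < self.r1 < self.r2:
            raise ValueError(f"need 0 < r1 < r2, got r1={self.r1}, r2={self.r2}")

    @property
    def delta_r(self) -> float:
        return self.r2 - self.r1


#: Probe layouts used by the wearable. ``default`` is the as-built layout
#: (4.2 / 20.1 mm); ``nominal_4_20`` is the round-number bench layout.
GEOMETRY_PRESETS: dict[str, ProbeGeometry] = {
    "default": ProbeGeometry(4.2, 20.1),
    "nominal_4_20": ProbeGeometry(4.0, 20.0),
}
DEFAULT_GEOMETRY = GEOMETRY_PRESETS["default"]


def effective_attenuation(props: OpticalProperties) -> float:
    """Return μeff = sqrt(3·μa·μs′) in mm⁻¹."""
    return props.mu_eff


def transport_mfp(props: OpticalProperties) -> float:
    """Transport mean free path 1/(μa+μs′) in mm.

    The distance over which photon direction randomizes; the diffusion
    approximation needs source-detector separations of several of these.
    """
    total = props.mu_a + props.mu_s_prime
    if total <= 0:
        raise ValueError("mu_a + mu_s_prime must be positive")
    return 1.0 / total


def distance_in_mfp(distance: float, props: OpticalProperties) -> float:
    """Express ``distance`` (mm) as a multiple of the transport mean free path."""
    if distance <= 0:
        raise ValueError(f"distance must be > 0, got {distance}")
    return distance / transport_mfp(props)


def format_mfp_multiple(value: float, decimals: int = 1, mode: str = "round") -> float:
    """Round or truncate an MFP multiple to a reporting precision.

    ``mode='round'`` is half-even rounding; ``mode='trunc'`` drops digits,
    which some reports use for values sitting just under a validity bound.
    """
    if mode == "round":
        return round(value, decimals)
    if mode == "trunc":
        factor = 10.0**decimals
        return math.trunc(value * factor) / factor
    raise ValueError(f"mode must be 'round' or 'trunc', got {mode!r}")


def reflectance(props: OpticalProperties, r):
    """Diffuse reflectance of a semi-infinite medium at distance ``r`` (mm).

    Implements ``(3/(2π r²))·(1 + (2/3)A)·μa·μs′·exp(−μeff·r)`` in arbitrary
    linear units. Only ratios of this quantity are used downstream, so the
    constant prefactor (including the boundary factor ``A``) carries no
    physical weight.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("source-detector distance r must be > 0")
    prefactor = (
        3.0
        / (2.0 * math.pi * r**2)
        * (1.0 + (2.0 / 3.0) * props.boundary_A)
        * props.mu_a
        * props.mu_s_prime
    )
    out = prefactor * np.exp(-props.mu_eff * r)
    return float(out) if out.ndim == 0 else out


def invert_mu_eff(R1: float, R2: float, geom: ProbeGeometry = DEFAULT_GEOMETRY) -> float:
    """Invert μeff (mm⁻¹) from near/far radiant-flux readings.

    ``μeff = ln((R1·r1²)/(R2·r2²)) / (r2 − r1)``. The result is invariant to
    any common gain applied to both readings. A negative value (R1·r1² <
    R2·r2², unphysical for a semi-infinite medium) is returned but flagged
    with :class:`NegativeAttenuationWarning` so noisy streams keep flowing.
    """
    if R1 <= 0 or R2 <= 0:
        raise ValueError("detector fluxes must be positive (sensor fault?)")
    mu = math.log((R1 * geom.r1**2) / (R2 * geom.r2**2)) / geom.delta_r
    if mu < 0:
        warnings.warn(
            f"inverted mu_eff is negative ({mu:.4g} mm^-1): R1*r1^2 < R2*r2^2",
            NegativeAttenuationWarning,
            stacklevel=2,
        )
    return mu


@dataclass(frozen=True)
class RepeatSummary:
    """Mean and relative standard deviation of repeated μeff estimates."""

    values: tuple
    mean: float  # rounded to the reporting precision
    mean_raw: float
    rsd: float  # percent, from unrounded values
    ndigits: int = field(default=3, repr=False)


def summarize_repeats(values, ndigits: int = 3) -> RepeatSummary:
    """Summarize repeated measurements: mean (reported at ``ndigits``) and RSD %.

    Mirrors the repeat-and-average protocol: a handful of consecutive
    estimates are averaged to the final reported value; the relative standard
    deviation (sample SD over mean, in percent) quantifies repeatability.
    """
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("need at least 2 repeats to summarize")
    mean_raw = statistics.fmean(vals)
    sd = statistics.stdev(vals)
    if mean_raw == 0:
        raise ValueError("mean of repeats is zero; RSD undefined")
    rsd = 100.0 * sd / abs(mean_raw)
    return RepeatSummary(
        values=vals, mean=round(mean_raw, ndigits), mean_raw=mean_raw, rsd=rsd, ndigits=ndigits
    )
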