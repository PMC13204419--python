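"""Steady-state Pennes bioheat solutions for depth-resolved tissue temperature.

For a one-dimensional semi-infinite perfused tissue (z ≥ 0) with light
absorbed as a Beer-Lambert source, the steady Pennes balance is

    k·d²T/dz² + μa·φ0·e^{−μeff·z} + ρb·cb·wb·(Ta − T) = 0

With m² = ρb·cb·wb / k and boundary conditions T(0) = Ts (measured surface
temperature) and T(∞) = T0 (core temperature, equal to the arterial
temperature Ta), the analytic solution is

    T(z) = T0 + (us + C)·e^{−m·z} − C·e^{−μeff·z},
    C = μa·φ0 / (k·(μeff² − m²)),  us = Ts − T0

In the usual regime μeff ≫ m the optical source term is a small correction
and the profile reduces to the perfusion-dominated form

    T(z) ≈ T0 + (Ts − T0)·e^{−m·z}

which maps a surface temperature stream directly onto depth: each time
sample is treated quasi-statically (the steady solution evaluated at the
instantaneous Ts), so depth oscillations shrink by exactly e^{−m·z}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tissue_optics import OpticalProperties

__all__ = [
    "ThermalProperties",
    "SurfaceHeating",
    "DEFAULT_M",
    "DEFAULT_T_CORE",
    "m_param",
    "steady_profile_full",
    "steady_profile_simple",
    "depth_series",
]

DEFAULT_M = 0.0876  # mm^-1, typical perfusion decay constant
DEFAULT_T_CORE = 36.5  # °C


@dataclass(frozen=True)
class ThermalProperties:
    """Pennes-equation parameters in the fixed mm / W / °C unit system.

    ``perfusion_product`` is ρb·cb·wb (blood density x specific heat x
    perfusion rate), W·mm⁻³·°C⁻¹. The decay constant ``m`` is
    sqrt(perfusion_product / k_tissue) unless ``m_override`` pins it (the
    typical value 0.0876 mm⁻¹ is used when only the simple profile is
    needed and the individual constants are unknown).
    """

    k_tissue: float = 5.0e-4  # W·mm⁻¹·°C⁻¹ (0.5 W·m⁻¹·K⁻¹, soft tissue)
    perfusion_product: float = DEFAULT_M**2 * 5.0e-4
    T_core: float = DEFAULT_T_CORE
    m_override: float | None = None

    def __post_init__(self) -> None:
        if self.k_tissue <= 0:
            raise ValueError(f"k_tissue must be > 0, got {self.k_tissue}")
        if self.perfusion_product < 0:
            raise ValueError(f"perfusion_product must be >= 0, got {self.perfusion_product}")
        if self.m_override is not None and self.m_override < 0:
            raise ValueError(f"m_override must be >= 0, got {self.m_override}")

    @property
    def m(self) -> float:
        """Perfusion decay constant, mm⁻¹."""
        if self.m_override is not None:
            return self.m_override
        return math.sqrt(self.perfusion_product / self.k_tissue)


@dataclass(frozen=True)
class SurfaceHeating:
    """Optical surface drive: incident fluence rate φ0 and measured Ts."""

    T_surface: float
    phi0: float = 0.0  # W·mm⁻²; 0 selects the perfusion-only (simple) regime

    def __post_init__(self) -> None:
        if self.phi0 < 0:
            raise ValueError(f"phi0 must be >= 0, got {self.phi0}")


def m_param(thermal: ThermalProperties) -> float:
    """Return the perfusion decay constant m = sqrt(ρbcbwb/k), mm⁻¹."""
    return thermal.m


def steady_profile_full(
    z,
    thermal: ThermalProperties,
    optics: OpticalProperties,
    heat: SurfaceHeating,
):
    """Full analytic steady Pennes profile T(z) in °C.

    Requires μeff ≠ m (the printed solution's two exponentials must be
    distinct; the resonant case would need a z·e^{−mz} term).
    """
    z = np.asarray(z, dtype=float)
    m = thermal.m
    mu = optics.mu_eff
    us = heat.T_surface - thermal.T_core
    if math.isclose(mu, m, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError(
            f"resonant case mu_eff == m ({mu:.6g} mm^-1) is outside this solution"
        )
    C = optics.mu_a * heat.phi0 / (thermal.k_tissue * (mu**2 - m**2))
    out = thermal.T_core + (us + C) * np.exp(-m * z) - C * np.exp(-mu * z)
    return float(out) if out.ndim == 0 else out


def steady_profile_simple(z, Ts: float, T0: float = DEFAULT_T_CORE, m: float = DEFAULT_M):
    """Perfusion-dominated profile T(z) = T0 + (Ts − T0)·e^{−m·z} in °C."""
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    z = np.asarray(z, dtype=float)
    out = T0 + (Ts - T0) * np.exp(-m * z)
    return float(out) if out.ndim == 0 else out


def depth_series(
    ts_series,
    depths,
    T0: float = DEFAULT_T_CORE,
    m: float = DEFAULT_M,
) -> pd.DataFrame:
    """Map a surface-temperature time series onto tissue depths.

    ``ts_series`` is a sequence of (timestamp_s, Ts_degC) pairs or a
    DataFrame with ``timestamp_s`` / ``temp_c`` columns. Each time point is
    treated quasi-statically, so column z is exactly
    ``steady_profile_simple(z, Ts(t))``: the depth-0 column reproduces the
    input and oscillation amplitudes shrink by e^{−m·z}.

    Returns a DataFrame indexed by ``timestamp_s`` with one ``z=<depth>mm``
    column per requested depth.
    """
    if isinstance(ts_series, pd.DataFrame):
        pairs = list(zip(ts_series["timestamp_s"], ts_series["temp_c"]))
    else:
        pairs = [(float(t), float(T)) for t, T in ts_series]
    if not pairs:
        raise ValueError("empty surface-temperature series")
    depths = [float(d) for d in depths]
    if any(d < 0 for d in depths):
        raise ValueError("depths must be >= 0")
    times = np.array([t for t, _ in pairs])
    ts = np.array([T for _, T in pairs])
    data = {f"z={d:g}mm": steady_profile_simple(d, ts, T0, m) for d in depths}
    return pd.DataFrame(data, index=pd.Index(times, name="timestamp_s"))
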