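"""Relative internal photon-fluence-rate reconstruction.

Far from an isotropic point source buried at depth ``z0 = 1/μs′`` under the
surface of a semi-infinite medium, a first-order (Taylor) expansion of the
dipole solution gives the internal fluence rate

    Φ(r, z) ≈ (P / 4πD) · 2(z0 + 2AD) · (z/R³) · (1 + μeff·R) · e^{−μeff·R}

with R = sqrt(r² + z²). The ratio of Φ at a target point to Φ at a fixed
shallow reference point depends only on μeff and the coordinates — P, D, A
and z0 all cancel — which is what makes a relative dose map recoverable from
a wearable's two-distance μeff estimate alone.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tissue_optics import OpticalProperties

__all__ = [
    "SourceModel",
    "FieldPoint",
    "FluenceField",
    "ValidityWarning",
    "fluence",
    "relative_fluence",
    "fluence_map",
    "axis_profile",
]

LOG_FLOOR = 1e-12  # display floor so the z=0 row stays plottable on log scale


class ValidityWarning(UserWarning):
    """Evaluation point violates the far-field assumption z0 << r, z."""


@dataclass(frozen=True)
class SourceModel:
    """Isotropic point source of power ``P`` (arbitrary units)."""

    P: float = 1.0

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError(f"source power must be > 0, got {self.P}")


@dataclass(frozen=True)
class FieldPoint:
    """A point inside the tissue: transverse distance r, depth z (mm)."""

    r: float
    z: float

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError(f"depth z must be >= 0, got {self.z}")

    @property
    def R(self) -> float:
        """Radial distance from the surface source, sqrt(r²+z²)."""
        return math.hypot(self.r, self.z)


def fluence(props: OpticalProperties, src: SourceModel, pt: FieldPoint) -> float:
    """Absolute-scale fluence rate at ``pt`` (arbitrary units).

    Vanishes identically at the surface (z = 0) under this approximation.
    Emits :class:`ValidityWarning` when ``R < z0`` — the expansion is not
    trustworthy that close to the source, though it remains finite.
    """
    R = pt.R
    if R == 0:
        raise ValueError("fluence is singular at the source point (r=z=0)")
    if R < props.z0:
        warnings.warn(
            f"point R={R:.3g} mm is inside one reduced scattering length "
            f"(z0={props.z0:.3g} mm); far-field expansion unreliable here",
            ValidityWarning,
            stacklevel=2,
        )
    D = props.diffusion_coefficient
    mu = props.mu_eff
    return (
        src.P
        / (4.0 * math.pi * D)
        * 2.0
        * (props.z0 + 2.0 * props.boundary_A * D)
        * (pt.z / R**3)
        * (1.0 + mu * R)
        * math.exp(-mu * R)
    )


def relative_fluence(mu_eff: float, target: FieldPoint, ref: FieldPoint) -> float:
    """Ratio Φ(target)/Φ(ref); depends only on μeff and the coordinates.

    ``(z₂R₁³)/(z₁R₂³) · (1+μeff·R₂)/(1+μeff·R₁) · e^{μeff(R₁−R₂)}``.
    The reference must be strictly below the surface (its fluence would
    otherwise be zero); a surface target returns 0.
    """
    if mu_eff < 0:
        raise ValueError(f"mu_eff must be >= 0, got {mu_eff}")
    if ref.z <= 0:
        raise ValueError("reference point must have z > 0 (zero fluence at surface)")
    if target.z == 0:
        return 0.0
    R1, R2 = ref.R, target.R
    return (
        (target.z * R1**3)
        / (ref.z * R2**3)
        * (1.0 + mu_eff * R2)
        / (1.0 + mu_eff * R1)
        * math.exp(mu_eff * (R1 - R2))
    )


@dataclass(frozen=True)
class FluenceField:
    """Relative fluence on an (r, z) grid, normalized to 1 at ``reference``."""

    r_axis: np.ndarray  # mm
    z_axis: np.ndarray  # mm
    values: np.ndarray  # shape (len(z_axis), len(r_axis)), dimensionless
    reference: FieldPoint
    mu_eff: float

    @property
    def log10_values(self) -> np.ndarray:
        """log10 of the field, floored at 1e-12 for display."""
        return np.log10(np.maximum(self.values, LOG_FLOOR))

    def to_csv(self, path) -> None:
        """Write the grid (header row = r axis, first column = z axis) plus a
        JSON metadata sidecar ``<path>.meta.json``."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["z_mm\\r_mm"] + [repr(float(r)) for r in self.r_axis])
            for z, row in zip(self.z_axis, self.values):
                writer.writerow([repr(float(z))] + [repr(float(v)) for v in row])
        meta = {
            "mu_eff_mm_inv": self.mu_eff,
            "reference": {"r_mm": self.reference.r, "z_mm": self.reference.z},
            "step_mm": float(self.r_axis[1] - self.r_axis[0]) if len(self.r_axis) > 1 else None,
            "normalization": "value 1 at reference cell",
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def fluence_map(
    mu_eff: float,
    r_range: tuple[float, float] = (-10.0, 10.0),
    z_range: tuple[float, float] = (0.0, 10.0),
    step: float = 0.1,
    ref: FieldPoint = FieldPoint(0.0, 1.0),
) -> FluenceField:
    """Relative-fluence map over an (r, z) grid, normalized at ``ref``.

    The default reference is a shallow point directly beneath the source,
    (r=0, z=1 mm). The grid cell containing the reference is pinned to
    exactly 1.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    r_axis = np.arange(r_range[0], r_range[1] + step / 2, step)
    z_axis = np.arange(z_range[0], z_range[1] + step / 2, step)
    if not (r_axis[0] <= ref.r <= r_axis[-1] and z_axis[0] <= ref.z <= z_axis[-1]):
        raise ValueError("reference point lies outside the requested grid")

    rr, zz = np.meshgrid(r_axis, z_axis)
    R = np.hypot(rr, zz)
    R1 = ref.R
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (
            (zz * R1**3)
            / (ref.z * R**3)
            * (1.0 + mu_eff * R)
            / (1.0 + mu_eff * R1)
            * np.exp(mu_eff * (R1 - R))
        )
    vals = np.where(zz == 0, 0.0, vals)  # surface row: z factor vanishes
    # pin the reference cell (guards against floating-point residue)
    iz = int(np.argmin(np.abs(z_axis - ref.z)))
    ir = int(np.argmin(np.abs(r_axis - ref.r)))
    vals[iz, ir] = 1.0
    return FluenceField(r_axis=r_axis, z_axis=z_axis, values=vals, reference=ref, mu_eff=mu_eff)


def axis_profile(
    field: FluenceField, axis: str, z_eps: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalized 1-D profile of a fluence field.

    ``axis='surface'`` returns intensity vs r on the shallow slice z = z_eps
    (the literal surface row is identically zero under this model, so a fixed
    shallow slice stands in for it; the r-shape is preserved because the z
    factor is constant along the slice). ``axis='depth'`` returns intensity
    vs z at r = 0. Both curves are normalized to a maximum of 1.
    """
    if axis == "surface":
        iz = int(np.argmin(np.abs(field.z_axis - z_eps)))
        coords, curve = field.r_axis, field.values[iz, :]
    elif axis == "depth":
        ir = int(np.argmin(np.abs(field.r_axis - 0.0)))
        coords, curve = field.z_axis, field.values[:, ir]
    else:
        raise ValueError(f"axis must be 'surface' or 'depth', got {axis!r}")
    peak = curve.max()
    if peak <= 0:
        raise ValueError("profile is identically zero; cannot normalize")
    return coords.copy(), curve / peak
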