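"""Two-wavelength regional oxygen saturation (rSO2) from spatially resolved
optical density.

With OD(r) = −log10 R(r) and the semi-infinite diffuse-reflectance model,

    ∂OD/∂r = (1/ln10) · (sqrt(3·μa·μs′) + 2/r)

Replacing the derivative by the two-distance difference ΔOD/Δr and removing
the geometric 2/r term leaves a quantity proportional to μeff, so the squared
ratio across two wavelengths

    κ = [ (ΔOD_λ1 − 2Δr/(r_ref·ln10)) / (ΔOD_λ2 − 2Δr/(r_ref·ln10)) ]²

equals μa(λ1)/μa(λ2) when the reduced scattering is the same at both
wavelengths. Modeling absorption as an oxy/deoxy-hemoglobin mixture then
gives the saturation S solving

    εHbO2(λ1)·S + εHb(λ1)·(1−S) = κ · [εHbO2(λ2)·S + εHb(λ2)·(1−S)]

The correction distance ``r_ref`` defaults to the logarithmic mean
Δr/ln(r2/r1), for which the difference form of the 2/r term is exact under
the r⁻²·exp(−μeff·r) reflectance model (ΔOD = [μeff·Δr + 2·ln(r2/r1)]/ln10);
geometric-mean, midpoint and near-distance conventions are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .tissue_optics import ProbeGeometry, DEFAULT_GEOMETRY
from .telemetry import TelemetryRecord, records_to_frame

__all__ = [
    "ChromophoreSpectra",
    "ODSample",
    "Rso2Series",
    "DEFAULT_WAVELENGTH_PAIR",
    "optical_density",
    "reference_distance",
    "absorption_ratio",
    "rso2_from_ratio",
    "rso2_series",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)
DEFAULT_WAVELENGTH_PAIR = (730.0, 855.0)


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Molar extinction coefficients of HbO2 and Hb at the probe wavelengths.

    Units are consistent across chromophores (the conventional cm⁻¹/M);
    only ratios enter the saturation estimate, so the absolute scale and even
    the hemoglobin concentration drop out.
    """

    wavelengths: tuple
    eps_hbo2: tuple
    eps_hb: tuple

    def __post_init__(self) -> None:
        if not (len(self.wavelengths) == len(self.eps_hbo2) == len(self.eps_hb)):
            raise ValueError("wavelengths and extinction lists must have equal length")
        if any(b <= a for a, b in zip(self.wavelengths, self.wavelengths[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        if any(e <= 0 for e in self.eps_hbo2 + self.eps_hb):
            raise ValueError("extinction coefficients must be > 0")

    def eps(self, wavelength: float) -> tuple[float, float]:
        """(εHbO2, εHb) at ``wavelength`` (exact match required)."""
        for wl, eo, eh in zip(self.wavelengths, self.eps_hbo2, self.eps_hb):
            if math.isclose(wl, wavelength, abs_tol=0.5):
                return eo, eh
        raise KeyError(f"no extinction entry at {wavelength} nm (have {self.wavelengths})")

    def mixture_mu_a(self, wavelength: float, saturation: float, total_hb_molar: float) -> float:
        """Absorption coefficient (mm⁻¹) of an S : (1−S) HbO2/Hb mixture."""
        eo, eh = self.eps(wavelength)
        eps_mix = eo * saturation + eh * (1.0 - saturation)
        # base-10 cm^-1/M extinction -> natural-log mm^-1 absorption
        return LN10 * eps_mix * total_hb_molar / 10.0

    @classmethod
    def default_table(cls) -> "ChromophoreSpectra":
        """Compiled literature extinction values at 730/810/855 nm (cm⁻¹/M).

        Approximate values from the standard hemoglobin compilation; every
        quantitative result in this package uses ratio round trips, so
        nothing depends on their absolute accuracy.
        """
        return cls(
            wavelengths=(730.0, 810.0, 855.0),
            eps_hbo2=(390.0, 864.0, 1072.0),
            eps_hb=(1102.2, 717.1, 691.3),
        )


@dataclass(frozen=True)
class ODSample:
    """Near/far optical densities of one wavelength at one time point."""

    wavelength: float
    od_near: float
    od_far: float
    timestamp: float

    @property
    def delta_od(self) -> float:
        return self.od_far - self.od_near


@dataclass(frozen=True)
class Rso2Series:
    """Time series of regional oxygen saturation estimates (fractions)."""

    timestamps: np.ndarray
    rso2: np.ndarray
    flags: tuple  # per-sample tuple of str flags, e.g. ('clipped_high',)

    def __post_init__(self) -> None:
        if not (len(self.timestamps) == len(self.rso2) == len(self.flags)):
            raise ValueError("timestamps, rso2 and flags must have equal length")


def optical_density(R) -> float:
    """OD = −log10(R) of a relative flux; R must be positive."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("flux must be > 0 to form an optical density")
    out = -np.log10(R)
    return float(out) if out.ndim == 0 else out


def reference_distance(geom: ProbeGeometry, mode: str = "log-mean") -> float:
    """Distance r_ref at which the 2/r geometric term is evaluated.

    ``log-mean`` (default): Δr/ln(r2/r1) — exact for the r⁻²·e^{−μeff r}
    model; ``geometric-mean``: sqrt(r1·r2); ``midpoint``: (r1+r2)/2;
    ``near``: r1.
    """
    if mode == "log-mean":
        return geom.delta_r / math.log(geom.r2 / geom.r1)
    if mode == "geometric-mean":
        return math.sqrt(geom.r1 * geom.r2)
    if mode == "midpoint":
        return 0.5 * (geom.r1 + geom.r2)
    if mode == "near":
        return geom.r1
    raise ValueError(f"unknown r_ref mode {mode!r}")


def _corrected(delta_od: float, geom: ProbeGeometry, r_ref: float) -> float:
    return delta_od - 2.0 * geom.delta_r / (r_ref * LN10)


def absorption_ratio(
    delta_od_l1: float,
    delta_od_l2: float,
    geom: ProbeGeometry = DEFAULT_GEOMETRY,
    r_ref: float | str = "log-mean",
) -> float:
    """Absorption-coefficient ratio κ = μa(λ1)/μa(λ2) from two ΔOD values.

    Both geometry-corrected terms must be nonzero and share a sign (each is
    proportional to that wavelength's μeff, hence positive for physical
    signals).
    """
    if isinstance(r_ref, str):
        r_ref = reference_distance(geom, r_ref)
    if r_ref <= 0:
        raise ValueError(f"r_ref must be > 0, got {r_ref}")
    num = _corrected(delta_od_l1, geom, r_ref)
    den = _corrected(delta_od_l2, geom, r_ref)
    scale = abs(delta_od_l1) + abs(delta_od_l2) + 1e-30
    if abs(den) < 1e-12 * scale:
        raise ValueError("corrected denominator is ~0: degenerate measurement")
    if num * den <= 0:
        raise ValueError(
            "corrected ΔOD terms differ in sign; measurement violates the "
            "positive-attenuation assumption"
        )
    return (num / den) ** 2


def rso2_from_ratio(
    kappa: float,
    spectra: ChromophoreSpectra,
    l1: float = DEFAULT_WAVELENGTH_PAIR[0],
    l2: float = DEFAULT_WAVELENGTH_PAIR[1],
) -> float:
    """Saturation S solving the two-wavelength hemoglobin mixture equation.

    ``S = (εHb(λ1) − εHb(λ2)·κ) / (κ·(εHbO2(λ2) − εHb(λ2)) − (εHbO2(λ1) − εHb(λ1)))``

    κ equal to εHbO2(λ1)/εHbO2(λ2) gives exactly 1 (pure oxyhemoglobin),
    εHb(λ1)/εHb(λ2) gives exactly 0. The value is returned unclipped; stream
    processing clips and flags.
    """
    eo1, eh1 = spectra.eps(l1)
    eo2, eh2 = spectra.eps(l2)
    den = kappa * (eo2 - eh2) - (eo1 - eh1)
    if den == 0:
        raise ValueError("degenerate wavelength/κ combination: no unique saturation")
    return (eh1 - eh2 * kappa) / den


def _frame_rso2(group, geom, spectra, l1, l2, r_ref):
    """κ → S for one timestamp's 4-record frame; raises KeyError if incomplete."""
    flux = {}
    for rec in group:
        flux[(rec.wavelength_nm, rec.detector_id)] = rec.flux
    delta = {}
    for wl in (l1, l2):
        od_near = optical_density(flux[(wl, "near")])
        od_far = optical_density(flux[(wl, "far")])
        delta[wl] = od_far - od_near
    kappa = absorption_ratio(delta[l1], delta[l2], geom, r_ref)
    return rso2_from_ratio(kappa, spectra, l1, l2)


def rso2_series(
    telemetry,
    geom: ProbeGeometry = DEFAULT_GEOMETRY,
    spectra: ChromophoreSpectra | None = None,
    wavelength_pair: tuple[float, float] = DEFAULT_WAVELENGTH_PAIR,
    r_ref: float | str = "log-mean",
) -> Rso2Series:
    """Run the flux → OD → ΔOD → κ → rSO2 pipeline over a telemetry stream.

    The stream must contain, per time point, both wavelengths at both
    detectors. Frames missing a wavelength/detector combination are skipped
    and logged. Estimates outside [0, 1] are clipped and flagged
    (``clipped_low`` / ``clipped_high``); noise near the admissible boundary
    is expected and should not abort a monitoring session.
    """
    if spectra is None:
        spectra = ChromophoreSpectra.default_table()
    l1, l2 = wavelength_pair
    df = records_to_frame(telemetry)
    if df.empty:
        raise ValueError("empty telemetry stream")

    times, sats, flags = [], [], []
    n_skipped = 0
    records = [TelemetryRecord(**row) for row in df.to_dict("records")]
    by_time: dict[float, list] = {}
    for rec in records:
        by_time.setdefault(rec.timestamp_s, []).append(rec)
    for t in sorted(by_time):
        try:
            s = _frame_rso2(by_time[t], geom, spectra, l1, l2, r_ref)
        except KeyError as exc:
            n_skipped += 1
            logger.warning("t=%s s: incomplete frame (missing %s); skipped", t, exc)
            continue
        frame_flags = []
        if s < 0.0:
            s, frame_flags = 0.0, ["clipped_low"]
        elif s > 1.0:
            s, frame_flags = 1.0, ["clipped_high"]
        times.append(t)
        sats.append(s)
        flags.append(tuple(frame_flags))
    if n_skipped:
        logger.warning("skipped %d incomplete frame(s)", n_skipped)
    if not times:
        raise ValueError("no complete two-wavelength, two-detector frames in stream")
    return Rso2Series(
        timestamps=np.asarray(times, dtype=float),
        rso2=np.asarray(sats, dtype=float),
        flags=tuple(flags),
    )
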