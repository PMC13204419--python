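"""Session configuration and the end-to-end processing pipeline.

``run_pipeline`` glues the stages together the way the wearable's firmware
would: (optionally) simulate phantom telemetry, invert μeff per wavelength
from repeated two-distance readings, reconstruct the relative fluence map,
estimate the rSO2 series from an occlusion stream, and project the surface
temperature series onto depth via the bioheat model. Each stage is isolated:
a failure is recorded in the report and only its dependents are skipped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import bioheat, oximetry, phantom as phantom_mod, tissue_optics
from .fluence import axis_profile, fluence_map
from .telemetry import write_telemetry
from .tissue_optics import GEOMETRY_PRESETS, ProbeGeometry

__all__ = ["SessionConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SessionConfig:
    """Everything one monitoring/simulation session needs.

    ``geometry`` is a preset name from :data:`GEOMETRY_PRESETS`;
    ``extinction_table`` may be None (ship the built-in table), a path to a
    CSV with wavelength_nm/eps_hbo2/eps_hb columns, or the string
    ``"missing"`` to model a deployment without one (the rSO2 stage then
    degrades gracefully).
    """

    geometry: str = "default"
    wavelengths: tuple[float, ...] = (730.0, 810.0, 855.0)
    wavelength_pair: tuple[float, float] = (730.0, 855.0)
    extinction_table: str | None = None
    m: float = bioheat.DEFAULT_M
    T0: float = bioheat.DEFAULT_T_CORE
    depths_mm: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0)
    grid_r_mm: tuple[float, float] = (-10.0, 10.0)
    grid_z_mm: tuple[float, float] = (0.0, 10.0)
    grid_step_mm: float = 0.1
    noise_rsd: float = 0.3
    n_repeats: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRY_PRESETS:
            raise ValueError(
                f"unknown geometry preset {self.geometry!r}; have {sorted(GEOMETRY_PRESETS)}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    @property
    def probe(self) -> ProbeGeometry:
        return GEOMETRY_PRESETS[self.geometry]

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("wavelengths", "wavelength_pair", "depths_mm", "grid_r_mm", "grid_z_mm"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_spectra(config: SessionConfig):
    if config.extinction_table is None:
        return oximetry.ChromophoreSpectra.default_table()
    if config.extinction_table == "missing":
        raise FileNotFoundError("no extinction table configured")
    import pandas as pd

    df = pd.read_csv(config.extinction_table).sort_values("wavelength_nm")
    return oximetry.ChromophoreSpectra(
        wavelengths=tuple(df["wavelength_nm"]),
        eps_hbo2=tuple(df["eps_hbo2"]),
        eps_hb=tuple(df["eps_hb"]),
    )


def run_pipeline(config: SessionConfig) -> dict:
    """Simulate → invert μeff → fluence map → rSO2 → bioheat, with per-stage
    error isolation. Returns a JSON-serializable report; with a fixed seed
    the report is bitwise reproducible."""
    report: dict = {"config": asdict(config), "stages": {}, "errors": {}}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    spec = phantom_mod.forearm_phantom(seed=config.seed, noise_rsd=config.noise_rsd)
    geom = config.probe

    # --- stage: simulate + invert mu_eff per wavelength -----------------
    inversions = {}
    try:
        for wl in config.wavelengths:
            truth = spec.optics_at(wl).mu_eff
            estimates = []
            for rep in range(config.n_repeats):
                rep_spec = phantom_mod.PhantomSpec(
                    optics=spec.optics,
                    saturation=spec.saturation,
                    total_hb_molar=spec.total_hb_molar,
                    noise_rsd=spec.noise_rsd,
                    seed=int(config.seed + 1000 * rep + int(wl)),
                )
                recs = phantom_mod.generate_detector_readings(rep_spec, geom, wl, n=1)
                near = next(r for r in recs if r.detector_id == "near")
                far = next(r for r in recs if r.detector_id == "far")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", tissue_optics.NegativeAttenuationWarning)
                    estimates.append(tissue_optics.invert_mu_eff(near.flux, far.flux, geom))
                if out_dir:
                    write_telemetry(recs, out_dir / f"telemetry_{int(wl)}nm_rep{rep}.csv")
            summary = tissue_optics.summarize_repeats(estimates)
            inversions[str(int(wl))] = {
                "wavelength_nm": wl,
                "mu_eff_mm_inv": summary.mean_raw,
                "mu_eff_true_mm_inv": truth,
                "n_repeats": config.n_repeats,
                "mean": summary.mean,
                "rsd_percent": summary.rsd,
                "flags": [],
            }
        report["stages"]["invert_mu_eff"] = inversions
    except Exception as exc:  # noqa: BLE001 - stage isolation by contract
        logger.exception("invert_mu_eff stage failed")
        report["errors"]["invert_mu_eff"] = str(exc)

    # --- stage: fluence map (depends on inversion) ----------------------
    if "invert_mu_eff" in report["stages"]:
        try:
            wl0 = str(int(config.wavelengths[0]))
            mu = inversions[wl0]["mu_eff_mm_inv"]
            fmap = fluence_map(mu, config.grid_r_mm, config.grid_z_mm, config.grid_step_mm)
            _, depth_prof = axis_profile(fmap, "depth")
            report["stages"]["fluence_map"] = {
                "mu_eff_mm_inv": mu,
                "grid_shape": list(fmap.values.shape),
                "reference": {"r_mm": fmap.reference.r, "z_mm": fmap.reference.z},
                "depth_profile_z5mm": float(
                    depth_prof[int(np.argmin(np.abs(fmap.z_axis - 5.0)))]
                ),
            }
            if out_dir:
                fmap.to_csv(out_dir / "fluence_map.csv")
        except Exception as exc:  # noqa: BLE001
            logger.exception("fluence_map stage failed")
            report["errors"]["fluence_map"] = str(exc)
    else:
        report["errors"].setdefault("fluence_map", "skipped: invert_mu_eff failed")

    # --- stage: rSO2 series ---------------------------------------------
    try:
        spectra = _load_spectra(config)
        stream = phantom_mod.occlusion_series(spec, geom=geom, spectra=spectra)
        series = oximetry.rso2_series(
            stream, geom, spectra, wavelength_pair=config.wavelength_pair
        )
        i_min = int(np.argmin(series.rso2))
        report["stages"]["rso2"] = {
            "n_samples": int(len(series.rso2)),
            "baseline": float(series.rso2[0]),
            "minimum": float(series.rso2[i_min]),
            "minimum_time_s": float(series.timestamps[i_min]),
            "final": float(series.rso2[-1]),
            "n_clipped": int(sum(1 for f in series.flags if f)),
        }
        if out_dir:
            import pandas as pd

            pd.DataFrame(
                {
                    "timestamp_s": series.timestamps,
                    "rso2": series.rso2,
                    "flags": [";".join(f) for f in series.flags],
                }
            ).to_csv(out_dir / "rso2_series.csv", index=False)
    except FileNotFoundError as exc:
        logger.warning("rSO2 stage skipped: %s", exc)
        report["errors"]["rso2"] = f"skipped: {exc}"
    except Exception as exc:  # noqa: BLE001
        logger.exception("rso2 stage failed")
        report["errors"]["rso2"] = str(exc)

    # --- stage: bioheat depth series ------------------------------------
    try:
        t = np.arange(0.0, 360.0, 5.0)
        on = (t % 240.0) < 120.0  # 2 min on / 2 min off drive
        ts = config.T0 + np.where(on, 3.0, 0.5)
        frame = bioheat.depth_series(
            list(zip(t, ts)), config.depths_mm, T0=config.T0, m=config.m
        )
        amplitudes = {col: float(frame[col].max() - frame[col].min()) for col in frame}
        report["stages"]["bioheat"] = {
            "m_mm_inv": config.m,
            "T0_c": config.T0,
            "amplitude_by_depth_c": amplitudes,
        }
        if out_dir:
            frame.to_csv(out_dir / "depth_temperature.csv")
    except Exception as exc:  # noqa: BLE001
        logger.exception("bioheat stage failed")
        report["errors"]["bioheat"] = str(exc)

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
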