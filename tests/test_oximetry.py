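"""ΔOD → absorption ratio → rSO2 estimation pipeline."""

import math

import numpy as np
import pytest

from lightdose import (
    ChromophoreSpectra,
    OpticalProperties,
    ProbeGeometry,
    TelemetryRecord,
    absorption_ratio,
    forearm_phantom,
    occlusion_saturation,
    occlusion_series,
    optical_density,
    reflectance,
    rso2_from_ratio,
    rso2_series,
)
from lightdose.oximetry import LN10, reference_distance

PAIR = (730.0, 855.0)


def kappa_from_forward_model(mu_a_1, mu_a_2, mu_s_prime, geom):
    """Build ΔOD at both wavelengths from the reflectance model, then invert."""
    dods = []
    for mu_a in (mu_a_1, mu_a_2):
        props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s_prime)
        dods.append(
            optical_density(reflectance(props, geom.r2))
            - optical_density(reflectance(props, geom.r1))
        )
    return absorption_ratio(dods[0], dods[1], geom)


class TestOpticalDensity:
    @pytest.mark.parametrize("R, od", [(1.0, 0.0), (0.01, 2.0), (10 ** (-0.5), 0.5)])
    def test_definition(self, R, od):
        assert optical_density(R) == pytest.approx(od, abs=1e-12)

    def test_nonpositive_flux_rejected(self):
        with pytest.raises(ValueError):
            optical_density(0.0)


class TestAbsorptionRatio:
    def test_equal_delta_od_gives_unity(self, probe):
        assert absorption_ratio(1.3, 1.3, probe) == pytest.approx(1.0)

    def test_forward_construction_from_derivative(self, probe):
        """ΔOD built from ∂OD/∂r = (1/ln10)(sqrt(3 μa μs′) + 2/r) at any r_ref
        inverts to the exact absorption ratio."""
        mu_s_prime = 1.2
        for mode in ("log-mean", "geometric-mean", "midpoint", "near"):
            r_ref = reference_distance(probe, mode)
            dods = [
                probe.delta_r / LN10 * (math.sqrt(3 * mu_a * mu_s_prime) + 2 / r_ref)
                for mu_a in (0.02, 0.01)
            ]
            kappa = absorption_ratio(dods[0], dods[1], probe, r_ref=mode)
            assert kappa == pytest.approx(2.0, rel=1e-12)

    def test_log_mean_exact_under_reflectance_model(self, probe):
        """With the default (log-mean) r_ref the full forward model inverts
        exactly; the geometric-mean convention leaves a residual bias."""
        kappa = kappa_from_forward_model(0.02, 0.01, 1.2, probe)
        assert kappa == pytest.approx(2.0, rel=1e-12)

    def test_degenerate_denominator_rejected(self, probe):
        r_ref = reference_distance(probe, "log-mean")
        corr = 2.0 * probe.delta_r / (r_ref * LN10)
        with pytest.raises(ValueError):
            absorption_ratio(corr + 1.0, corr, probe)

    def test_sign_mismatch_rejected(self, probe):
        r_ref = reference_distance(probe, "log-mean")
        corr = 2.0 * probe.delta_r / (r_ref * LN10)
        with pytest.raises(ValueError):
            absorption_ratio(corr + 0.5, corr - 0.5, probe)


class TestRso2FromRatio:
    def test_pure_oxyhemoglobin_limit(self, spectra):
        eo1, _ = spectra.eps(730.0)
        eo2, _ = spectra.eps(855.0)
        assert rso2_from_ratio(eo1 / eo2, spectra) == pytest.approx(1.0, abs=1e-12)

    def test_pure_deoxyhemoglobin_limit(self, spectra):
        _, eh1 = spectra.eps(730.0)
        _, eh2 = spectra.eps(855.0)
        assert rso2_from_ratio(eh1 / eh2, spectra) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("S", np.round(np.arange(0.1, 0.91, 0.1), 2))
    def test_mixture_round_trip(self, S, spectra):
        eo1, eh1 = spectra.eps(730.0)
        eo2, eh2 = spectra.eps(855.0)
        kappa = (eo1 * S + eh1 * (1 - S)) / (eo2 * S + eh2 * (1 - S))
        assert rso2_from_ratio(kappa, spectra) == pytest.approx(S, abs=1e-9)

    def test_monotone_in_kappa_between_limits(self, spectra):
        eo1, eh1 = spectra.eps(730.0)
        eo2, eh2 = spectra.eps(855.0)
        k_hb, k_hbo2 = eh1 / eh2, eo1 / eo2
        kappas = np.linspace(min(k_hb, k_hbo2) + 1e-6, max(k_hb, k_hbo2) - 1e-6, 50)
        sats = [rso2_from_ratio(k, spectra) for k in kappas]
        diffs = np.diff(sats)
        assert np.all(diffs < 0) or np.all(diffs > 0)

    def test_unknown_wavelength_rejected(self, spectra):
        with pytest.raises(KeyError):
            rso2_from_ratio(1.0, spectra, l1=700.0)


class TestRso2Series:
    def test_constant_stream_gives_constant_series(self, quiet_phantom, probe):
        stream = occlusion_series(quiet_phantom, drop_to=quiet_phantom.saturation, geom=probe)
        series = rso2_series(stream, probe)
        np.testing.assert_allclose(series.rso2, quiet_phantom.saturation, atol=1e-12)

    def test_noise_free_occlusion_recovered_pointwise(self, quiet_phantom, probe):
        """flux → OD → κ → S reproduces the generating saturation trajectory."""
        stream = occlusion_series(quiet_phantom, drop_to=0.45, geom=probe)
        series = rso2_series(stream, probe)
        truth = occlusion_saturation(series.timestamps, quiet_phantom.saturation, 0.45)
        np.testing.assert_allclose(series.rso2, truth, atol=1e-6)

    def test_occlusion_shape(self, probe):
        """Dip after contraction, minimum just before release, recovery to
        baseline within 2% by the end of the episode."""
        phantom = forearm_phantom(seed=3, noise_rsd=0.1)
        stream = occlusion_series(phantom, drop_to=0.45, geom=probe)
        series = rso2_series(stream, probe)
        t_min = series.timestamps[int(np.argmin(series.rso2))]
        assert 8.0 <= t_min <= 12.0
        baseline = phantom.saturation
        assert abs(series.rso2[-1] - baseline) <= 0.02 * baseline

    def test_common_gain_leaves_series_unchanged(self, quiet_phantom, probe):
        stream = occlusion_series(quiet_phantom, drop_to=0.5, geom=probe)
        scaled = [
            TelemetryRecord(
                r.timestamp_s, r.wavelength_nm, r.detector_id, r.distance_mm, r.flux * 37.5
            )
            for r in stream
        ]
        a, b = rso2_series(stream, probe), rso2_series(scaled, probe)
        np.testing.assert_allclose(a.rso2, b.rso2, rtol=1e-12)

    def test_single_wavelength_stream_has_no_frames(self, quiet_phantom, probe):
        stream = occlusion_series(quiet_phantom, drop_to=0.5, geom=probe)
        only_730 = [r for r in stream if r.wavelength_nm == 730.0]
        with pytest.raises(ValueError, match="no complete"):
            rso2_series(only_730, probe)

    def test_incomplete_frames_skipped(self, quiet_phantom, probe, caplog):
        stream = occlusion_series(quiet_phantom, drop_to=0.5, geom=probe)
        t_drop = stream[0].timestamp_s
        broken = [
            r
            for r in stream
            if not (r.timestamp_s == t_drop and r.wavelength_nm == 855.0)
        ]
        series = rso2_series(broken, probe)
        full = rso2_series(stream, probe)
        assert len(series.rso2) == len(full.rso2) - 1

    def test_out_of_range_values_clipped_and_flagged(self, probe, spectra):
        # fluxes whose kappa sits beyond the pure-HbO2 limit -> S > 1
        eo1, _ = spectra.eps(730.0)
        eo2, _ = spectra.eps(855.0)
        records = []
        for wl, mu_a in ((730.0, eo1 * 0.9), (855.0, eo2 * 1.3)):
            props = OpticalProperties(mu_a=mu_a * 1e-5, mu_s_prime=1.2)
            records.append(TelemetryRecord(0.0, wl, "near", probe.r1, reflectance(props, probe.r1)))
            records.append(TelemetryRecord(0.0, wl, "far", probe.r2, reflectance(props, probe.r2)))
        series = rso2_series(records, probe, spectra)
        assert series.rso2[0] in (0.0, 1.0)
        assert series.flags[0] in (("clipped_low",), ("clipped_high",))


class TestSpectraTable:
    def test_lookup_at_probe_wavelengths(self, spectra):
        for wl in (730.0, 810.0, 855.0):
            eo, eh = spectra.eps(wl)
            assert eo > 0 and eh > 0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ChromophoreSpectra((855.0, 730.0), (1.0, 2.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            ChromophoreSpectra((730.0, 855.0), (1.0, -2.0), (1.0, 2.0))
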