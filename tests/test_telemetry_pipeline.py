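"""Record I/O, safety monitoring and the end-to-end session pipeline."""

import dataclasses
import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from lightdose import (
    SessionConfig,
    TelemetryRecord,
    forearm_phantom,
    generate_detector_readings,
    read_telemetry,
    run_pipeline,
    safety_monitor,
    write_telemetry,
)
from lightdose.cli import main as cli_main


class TestTelemetryIO:
    def test_round_trip_lossless(self, tmp_path):
        recs = generate_detector_readings(forearm_phantom(seed=3), n=5)
        path = tmp_path / "t.csv"
        write_telemetry(recs, path)
        back = read_telemetry(path)
        for a, b in zip(recs, back):
            assert a.flux == b.flux  # full float precision
            assert (a.timestamp_s, a.wavelength_nm, a.detector_id) == (
                b.timestamp_s,
                b.wavelength_nm,
                b.detector_id,
            )

    def test_malformed_row_skipped_with_log(self, tmp_path, caplog):
        recs = generate_detector_readings(forearm_phantom(seed=3), n=3)
        path = tmp_path / "t.csv"
        write_telemetry(recs, path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace(lines[2].split(",")[4], "not-a-number", 1)
        path.write_text("\n".join(lines))
        with caplog.at_level("WARNING"):
            back = read_telemetry(path)
        assert len(back) == len(recs) - 1
        assert any("malformed" in r.message for r in caplog.records)

    def test_shuffled_timestamps_resorted(self, tmp_path, caplog):
        recs = generate_detector_readings(forearm_phantom(seed=3), n=4)
        path = tmp_path / "t.csv"
        write_telemetry(list(reversed(recs)), path)
        with caplog.at_level("WARNING"):
            back = read_telemetry(path)
        times = [r.timestamp_s for r in back]
        assert times == sorted(times)
        assert any("re-sorting" in r.message for r in caplog.records)

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("timestamp_s,flux\n0,1\n")
        with pytest.raises(ValueError, match="mandatory columns"):
            read_telemetry(path)

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_telemetry(path)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            TelemetryRecord(0.0, 730.0, "near", 4.2, -1.0)
        with pytest.raises(ValueError):
            TelemetryRecord(0.0, 730.0, "sideways", 4.2, 1.0)


class TestSafetyMonitor:
    def test_quiet_stream_no_events(self):
        events, on = safety_monitor([(t, 36.0 + 0.1 * t) for t in range(10)], 43.0)
        assert events == [] and on.all()

    def test_single_event_at_first_crossing(self):
        temps = [(float(k), 40.0 + 0.5 * k) for k in range(12)]  # crosses 43 at k=7
        events, on = safety_monitor(temps, 43.0)
        assert len(events) == 1
        assert events[0].index == 7
        assert not on[7:].any() and on[:7].all()

    def test_exact_threshold_does_not_fire(self):
        events, _ = safety_monitor([(0.0, 42.0), (1.0, 43.0), (2.0, 42.9)], 43.0)
        assert events == []

    def test_one_event_per_excursion(self):
        temps = [(0, 42.0), (1, 43.5), (2, 43.6), (3, 42.0), (4, 44.0), (5, 44.1)]
        events, on = safety_monitor(temps, 43.0)
        assert [e.index for e in events] == [1, 4]
        assert not on[1:].any()  # source stays off after the first trip


class TestPipeline:
    def test_default_session_recovers_phantom_attenuation(self, tmp_path):
        config = SessionConfig(seed=0, out_dir=str(tmp_path / "out"))
        report = run_pipeline(config)
        assert report["errors"] == {}
        for entry in report["stages"]["invert_mu_eff"].values():
            rel = abs(entry["mu_eff_mm_inv"] - entry["mu_eff_true_mm_inv"])
            assert rel / entry["mu_eff_true_mm_inv"] < 0.02
        assert (tmp_path / "out" / "report.json").exists()

    def test_zero_noise_session_is_exact(self):
        report = run_pipeline(SessionConfig(seed=1, noise_rsd=0.0))
        for entry in report["stages"]["invert_mu_eff"].values():
            assert entry["mu_eff_mm_inv"] == pytest.approx(
                entry["mu_eff_true_mm_inv"], rel=1e-12
            )

    def test_fixed_seed_reproducible(self):
        a = run_pipeline(SessionConfig(seed=4))
        b = run_pipeline(SessionConfig(seed=4))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_missing_extinction_table_degrades_gracefully(self):
        report = run_pipeline(SessionConfig(seed=0, extinction_table="missing"))
        assert "rso2" in report["errors"] and "skipped" in report["errors"]["rso2"]
        assert "invert_mu_eff" in report["stages"]
        assert "fluence_map" in report["stages"]
        assert "bioheat" in report["stages"]

    def test_occlusion_summary_shape(self):
        report = run_pipeline(SessionConfig(seed=2, noise_rsd=0.0))
        rso2 = report["stages"]["rso2"]
        assert rso2["minimum"] < rso2["baseline"]
        assert 8.0 <= rso2["minimum_time_s"] <= 12.0
        assert abs(rso2["final"] - rso2["baseline"]) < 0.02 * rso2["baseline"]

    def test_bioheat_amplitudes_shrink_with_depth(self):
        report = run_pipeline(SessionConfig(seed=0))
        amps = list(report["stages"]["bioheat"]["amplitude_by_depth_c"].values())
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(geometry="triangular")

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "session.yaml"
        cfg_path.write_text("geometry: nominal_4_20\nseed: 9\nnoise_rsd: 0.1\n")
        cfg = SessionConfig.from_yaml(cfg_path)
        assert cfg.probe.r1 == 4.0 and cfg.seed == 9 and cfg.noise_rsd == 0.1


class TestCli:
    def test_simulate_then_invert(self, tmp_path):
        runner = CliRunner()
        tele = tmp_path / "t.csv"
        r = runner.invoke(cli_main, ["simulate", "--seed", "0", "--out", str(tele), "--n", "5"])
        assert r.exit_code == 0, r.output
        out = tmp_path / "inv.json"
        r = runner.invoke(cli_main, ["invert-mueff", "--out", str(out), str(tele)])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        assert "730" in payload and payload["730"]["n_repeats"] == 5

    def test_monitor_reports_shutoff(self, tmp_path):
        recs = [
            TelemetryRecord(float(t), 730.0, "near", 4.2, 1.0, temp_c=41.0 + t)
            for t in range(5)
        ]
        tele = tmp_path / "t.csv"
        write_telemetry(recs, tele)
        runner = CliRunner()
        r = runner.invoke(cli_main, ["monitor", str(tele), "--threshold", "43"])
        assert r.exit_code == 0, r.output
        assert "SHUTOFF" in r.output
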