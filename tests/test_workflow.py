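"""End-to-end recipes, run configuration, file I/O and the CLI."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tissuelight.cli import main as cli_main
from tissuelight.io import (
    read_property_table,
    read_spectrum,
    read_trace,
    write_property_table,
    write_spectrum,
    write_trace,
)
from tissuelight.photothermal import LumpedThermalParams, simulate_heating
from tissuelight.synthetic import (
    default_property_table,
    gen_absorbance_spectra,
)
from tissuelight.workflow import RunConfig, run_depth_study, run_pce_recipe

SMALL = dict(n_photons=4_000, grid_nr=120)


def _dir_checksums(path: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.iterdir()) if p.is_file()}


class TestRunConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            RunConfig.from_mapping({"photons": 10})

    def test_yaml_and_json_round_trip(self, tmp_path):
        payload = {"wavelengths": [852.0], "fat_depths": [0.0, 2.0],
                   "n_photons": 500, "seed": 3}
        jpath = tmp_path / "cfg.json"
        jpath.write_text(json.dumps(payload))
        ypath = tmp_path / "cfg.yaml"
        ypath.write_text("wavelengths: [852.0]\nfat_depths: [0.0, 2.0]\n"
                         "n_photons: 500\nseed: 3\n")
        assert RunConfig.from_file(jpath) == RunConfig.from_file(ypath)

    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig.from_mapping({"n_photons": 0})


@pytest.fixture(scope="module")
def study(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    cfg = RunConfig(wavelengths=(808.0, 852.0, 890.0),
                    fat_depths=(0.0, 2.0), seed=5, out_dir=str(out), **SMALL)
    table = run_depth_study(cfg)
    return out, table


class TestDepthStudyRecipe:
    def test_row_count_is_wavelengths_x_depths_x_states(self, study):
        _, table = study
        assert len(table) == 3 * 2 * 2

    def test_agent_rows_dominate(self, study):
        _, table = study
        piv = table.pivot_table(index=["wavelength_nm", "fat_mm"], columns="agent",
                                values="peak_J_per_mm3")
        assert (piv[True] > piv[False]).all()

    def test_manifest_records_seed_and_config(self, study):
        out, _ = study
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["config"]["n_photons"] == SMALL["n_photons"]
        assert "depth_scan.csv" in manifest["artifacts"]

    def test_rerun_is_checksum_identical(self, tmp_path):
        cfg_kw = dict(wavelengths=(852.0,), fat_depths=(2.0,), seed=9, **SMALL)
        a, b = tmp_path / "a", tmp_path / "b"
        run_depth_study(RunConfig(out_dir=str(a), **cfg_kw))
        run_depth_study(RunConfig(out_dir=str(b), **cfg_kw))
        assert _dir_checksums(a) == _dir_checksums(b)


class TestPceRecipe:
    @pytest.fixture()
    def trace_files(self, tmp_path):
        p = LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0, Q_dis=6.0)
        tr = simulate_heating(p, 0.18, on_duration=1500, off_duration=900, dt=1.0)
        blank = simulate_heating(
            LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0, Q_dis=6.0),
            0.0, on_duration=1500, off_duration=900, dt=1.0)
        tpath, bpath = tmp_path / "trace.csv", tmp_path / "blank.csv"
        write_trace(tr, tpath)
        write_trace(blank, bpath)
        return tpath, bpath

    def test_recovery_with_blank(self, trace_files, tmp_path):
        tpath, bpath = trace_files
        cfg = RunConfig(m_g=0.3, C_p=4.18, I_mW=750.0, Abs_lambda=1.0)
        out = tmp_path / "pce.json"
        res = run_pce_recipe(tpath, bpath, cfg, out_path=out)
        assert res.eta == pytest.approx(0.18, rel=2e-3)
        payload = json.loads(out.read_text())
        assert payload["eta_percent"] == pytest.approx(18.0, rel=2e-3)

    def test_missing_blank_defaults_q_dis_zero(self, trace_files, caplog):
        tpath, _ = trace_files
        cfg = RunConfig(m_g=0.3, C_p=4.18, I_mW=750.0, Abs_lambda=1.0)
        with caplog.at_level("WARNING", logger="tissuelight"):
            res = run_pce_recipe(tpath, None, cfg)
        assert "Q_dis defaults to 0" in caplog.text
        # without the blank correction eta absorbs the background term
        assert res.eta > 0.18

    def test_malformed_trace_names_line(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("time_s,temp_C,laser_on\n0,25.0,1\n1,not_a_number,1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_trace(bad)


class TestIORoundTrips:
    def test_property_table(self, tmp_path):
        table = default_property_table()
        path = tmp_path / "props.csv"
        write_property_table(table, path)
        back = read_property_table(path)
        for name, layer in table.items():
            for wl, p in layer.props.items():
                q = back[name].at(wl)
                assert (q.mu_a, q.mu_s, q.g, q.n) == pytest.approx(
                    (p.mu_a, p.mu_s, p.g, p.n))

    def test_per_cm_units_converted(self, tmp_path):
        path = tmp_path / "props.csv"
        path.write_text(
            "layer,wavelength_nm,mua,mus,unit,g,n,thickness_mm\n"
            "slab,800,1.0,10.0,per_cm,0.9,1.37,1.0\n")
        layer = read_property_table(path)["slab"]
        assert layer.at(800.0).mu_a == pytest.approx(0.1)
        assert layer.at(800.0).mu_s == pytest.approx(1.0)

    def test_spectrum_round_trip(self, tmp_path):
        spec = gen_absorbance_spectra("monomer")
        path = tmp_path / "mono.csv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        assert np.allclose(back.epsilon, spec.epsilon)

    def test_trace_sidecar_carries_ambient(self, tmp_path):
        tr = simulate_heating(LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0),
                              0.1, 100, 100, 1.0)
        path = tmp_path / "t.csv"
        write_trace(tr, path, metadata={"I_mW": 750.0})
        back = read_trace(path)
        assert back.T_surr == tr.T_surr
        assert json.loads(path.with_suffix(".json").read_text())["I_mW"] == 750.0


class TestCli:
    def test_cem43_command(self, tmp_path):
        t = np.arange(0.0, 601.0, 1.0)
        trace_path = tmp_path / "trace.csv"
        pd.DataFrame({"time_s": t, "temp_C": np.full_like(t, 44.0),
                      "laser_on": 0}).to_csv(trace_path, index=False)
        res = CliRunner().invoke(cli_main, ["cem43", str(trace_path)])
        assert res.exit_code == 0
        assert "CEM43 = 20.0000 min" in res.output

    def test_ce_command(self, tmp_path):
        sig = tmp_path / "signals.csv"
        sig.write_text("timepoint_h,signal\nbaseline,2.0\n4,5.0\n8,4.0\n")
        res = CliRunner().invoke(cli_main, ["ce", str(sig)])
        assert res.exit_code == 0
        assert "t = 4 h: CE = 2.500" in res.output

    def test_synth_spectra_and_props(self, tmp_path):
        for what in ("spectra", "props"):
            res = CliRunner().invoke(
                cli_main, ["synth", what, "--out", str(tmp_path / what)])
            assert res.exit_code == 0, res.output
        assert (tmp_path / "spectra" / "j_aggregate.csv").exists()
        assert (tmp_path / "props" / "optical_properties.csv").exists()

    def test_pce_fit_command(self, tmp_path):
        tr = simulate_heating(LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0),
                              0.15, 1500, 900, 1.0)
        path = tmp_path / "trace.csv"
        write_trace(tr, path)
        res = CliRunner().invoke(cli_main, [
            "pce-fit", str(path), "--mass", "0.3", "--power", "750"])
        assert res.exit_code == 0, res.output
        assert "eta = 15.0" in res.output

    def test_validation_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("wrong,columns\n1,2\n")
        res = CliRunner().invoke(cli_main, ["cem43", str(bad)])
        assert res.exit_code == 1

    def test_simulate_light_smoke(self, tmp_path):
        out = tmp_path / "imp.csv"
        res = CliRunner().invoke(cli_main, [
            "simulate-light", "--wavelength", "852", "--fat", "1.0",
            "--photons", "2000", "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.exists() and out.with_suffix(".json").exists()
        meta = json.loads(out.with_suffix(".json").read_text())
        total = meta["R_sp"] + meta["R_d"] + meta["A_total"] + meta["T_t"]
        assert total == pytest.approx(1.0, abs=1e-3)
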