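"""CSV dialects, config validation, pipeline runs, CLI exit codes."""

import json

import numpy as np
import pandas as pd
import pytest

from casensor import (AnalysisConfig, NoiseSpec, gen_dose_response, gen_titration,
                      read_series, run_pipeline, write_series)
from casensor.cli import main as cli_main
from casensor.interface import ParseError


class TestReadSeries:
    def test_wellformed_titration(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("ca_total_uM,a263\n0,0.55\n3,0.5\n6,0.45\n9,0.4\n12,0.36\n15,0.33\n")
        s = read_series(p, "titration", {"q_total_uM": 25, "p_total_uM": 5})
        assert len(s) == 6
        assert s.ca_total[1] == pytest.approx(3e-6)
        assert s.q_total == pytest.approx(25e-6)

    def test_header_typo_names_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("ca_total_uM,a236\n0,0.55\n")
        with pytest.raises(ParseError, match="a263"):
            read_series(p, "titration")

    def test_non_numeric_row_reported_with_position(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("temp_C,theta222_mdeg\n20,-20\n21,oops\n")
        with pytest.raises(ParseError, match="row 2"):
            read_series(p, "melt")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_series(p, "titration")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_series(tmp_path / "nope.csv", "melt")

    def test_round_trip_identity(self, tmp_path, n104h_model):
        s1 = gen_titration(n104h_model, n_points=12,
                           noise=NoiseSpec("absolute", 0.01, 3))
        p = tmp_path / "rt.csv"
        write_series(s1, p, "titration")
        s2 = read_series(p, "titration",
                         {"q_total_uM": s1.q_total * 1e6, "p_total_uM": s1.p_total * 1e6})
        np.testing.assert_allclose(s2.ca_total, s1.ca_total, rtol=1e-12)
        np.testing.assert_allclose(s2.absorbance, s1.absorbance, rtol=1e-12)

    def test_dose_response_round_trip(self, tmp_path):
        s1 = gen_dose_response(0.52e-6, 1.77, 4.9, 1.0, "free_ca",
                               noise=NoiseSpec("proportional", 0.05, 1))
        p = tmp_path / "dr.csv"
        write_series(s1, p, "dose_response")
        s2 = read_series(p, "dose_response", {"axis": "free_ca"})
        np.testing.assert_allclose(s2.activity, s1.activity, rtol=1e-12)


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            AnalysisConfig.from_dict({"assay": "melt", "n_sights": 3})

    def test_defaults_filled(self):
        cfg = AnalysisConfig.from_dict({"assay": "melt"})
        assert cfg["n_sites"] == 3
        assert cfg["chelator_kd_uM"] == pytest.approx(2.3)

    def test_type_checked(self):
        with pytest.raises(ValueError, match="n_sites"):
            AnalysisConfig.from_dict({"n_sites": "three"})

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("assay: ca_inhibition\nsimulate: true\nnoise_sigma: 0.05\nseed: 7\n")
        cfg = AnalysisConfig.from_yaml(p)
        assert cfg["assay"] == "ca_inhibition"
        assert cfg["seed"] == 7


class TestPipeline:
    def test_simulate_then_analyze_ca_inhibition(self, tmp_path):
        cfg = AnalysisConfig.from_dict({
            "assay": "ca_inhibition", "simulate": True, "noise_sigma": 0.05,
            "seed": 3, "out_dir": str(tmp_path / "out")})
        bundle = run_pipeline(cfg)
        assert bundle["ok"]
        rows = {r["quantity"]: r["value"] for r in bundle["rows"]}
        assert rows["IC50"] == pytest.approx(0.52, rel=0.3)  # uM
        assert (tmp_path / "out" / "report.csv").exists()
        assert (tmp_path / "out" / "report.txt").exists()
        log = json.loads((tmp_path / "out" / "run_log.json").read_text())
        assert log["seed"] == 3 and "version" in log

    def test_missing_input_path_is_explicit_error(self, tmp_path):
        cfg = AnalysisConfig.from_dict({
            "assay": "melt", "data": str(tmp_path / "absent.csv"),
            "out_dir": str(tmp_path / "out")})
        bundle = run_pipeline(cfg)
        assert not bundle["ok"]
        assert "absent.csv" in bundle["error"]

    def test_same_seed_reproduces_numeric_report(self, tmp_path):
        outs = []
        for d in ("a", "b"):
            cfg = AnalysisConfig.from_dict({
                "assay": "melt", "simulate": True, "noise_sigma": 0.02,
                "seed": 11, "out_dir": str(tmp_path / d)})
            assert run_pipeline(cfg)["ok"]
            outs.append((tmp_path / d / "report.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_sec_pipeline(self, tmp_path):
        std = tmp_path / "std.csv"
        # standards on a clean log-linear law over the column geometry
        vol = np.array([10.0, 13.0, 16.0, 19.0])
        dc = (vol - 8.0) / (25.0 - 8.0)
        mw = 10 ** (2.2 - 1.8 * dc)
        pd.DataFrame({"mw_kDa": mw, "v_elute_mL": vol}).to_csv(std, index=False)
        runs = tmp_path / "runs.csv"
        pd.DataFrame({"sample": ["N104H_Mg"], "v_elute_mL": [14.2]}).to_csv(runs, index=False)
        cfg = AnalysisConfig.from_dict({
            "assay": "sec", "data": str(runs), "standards": str(std),
            "out_dir": str(tmp_path / "out")})
        bundle = run_pipeline(cfg)
        assert bundle["ok"]
        mw_est = bundle["rows"][0]["value"]
        expect = 10 ** (2.2 - 1.8 * (14.2 - 8.0) / 17.0)
        assert mw_est == pytest.approx(expect, rel=1e-6)


class TestCLI:
    def test_simulate_melt_exits_zero(self, tmp_path, capsys):
        rc = cli_main(["simulate", "melt", "--noise-sigma", "0.02",
                       "--seed", "4", "--out-dir", str(tmp_path / "o")])
        assert rc == 0
        assert "Tm" in capsys.readouterr().out

    def test_missing_input_exits_two(self, tmp_path):
        rc = cli_main(["fit-melt", str(tmp_path / "absent.csv"),
                       "--out-dir", str(tmp_path / "o")])
        assert rc == 2

    def test_fit_gc_on_written_fixture(self, tmp_path, capsys):
        s = gen_dose_response(1.6e-6, 2.0, 4.9, 1.0, "activator_conc",
                              noise=NoiseSpec("proportional", 0.05, 2))
        p = tmp_path / "act.csv"
        write_series(s, p, "dose_response")
        rc = cli_main(["fit-gc", str(p), "--axis", "activator_conc",
                       "--out-dir", str(tmp_path / "o")])
        assert rc == 0
        assert "EC50" in capsys.readouterr().out
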