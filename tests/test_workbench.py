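"""Configuration, orchestration, CLI round trips."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml

from ovoscope import eggsim
from ovoscope.workbench import RunConfig, cmd_analyze, cmd_measure, cmd_simulate


def write_config(path, **kw):
    path.write_text(yaml.safe_dump(kw))
    return path


class TestRunConfig:
    def test_unknown_keys_rejected(self, tmp_path):
        cfg = write_config(tmp_path / "c.yaml", seed=1, wibble=2)
        with pytest.raises(ValueError, match="wibble"):
            RunConfig.from_yaml(cfg)

    def test_seed_mandatory(self, tmp_path):
        cfg = write_config(tmp_path / "c.yaml", n_eggs=1)
        with pytest.raises(ValueError, match="seed"):
            RunConfig.from_yaml(cfg)

    def test_standard_value_validated(self):
        with pytest.raises(ValueError, match="standard_value"):
            RunConfig(seed=1, standard_value=150.0)


class TestSimulate:
    def test_deterministic_manifests(self, tmp_path):
        kw = dict(seed=9, n_eggs=1, noise_sd=0.0)
        a = cmd_simulate(RunConfig(output_dir=str(tmp_path / "a"), **kw))
        b = cmd_simulate(RunConfig(output_dir=str(tmp_path / "b"), **kw))
        ma = json.loads((a / "manifest.json").read_text())
        mb = json.loads((b / "manifest.json").read_text())
        assert ma == mb and len(ma) > 0

    def test_zero_eggs_is_valid(self, tmp_path):
        out = cmd_simulate(RunConfig(seed=1, n_eggs=0,
                                     output_dir=str(tmp_path / "z")))
        manifest = json.loads((out / "manifest.json").read_text())
        assert not any(k.endswith(".tif") for k in manifest)

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            cmd_simulate(RunConfig(seed=1, n_eggs=0, output_dir=str(out)))
        cmd_simulate(
            RunConfig(seed=1, n_eggs=0, output_dir=str(out)), force=True
        )

    def test_default_trait_table_has_study_size(self, tmp_path):
        out = cmd_simulate(RunConfig(seed=2, n_eggs=0,
                                     output_dir=str(tmp_path / "t")))
        table = pd.read_csv(out / "traits_truth.csv")
        assert 70 <= len(table) <= 150  # Poisson around 110


class TestMeasure:
    @pytest.fixture(scope="class")
    def fixture_dir(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("fixtures")
        cfg = RunConfig(seed=4, n_eggs=2, noise_sd=0.0,
                        output_dir=str(out))
        return cmd_simulate(cfg), cfg

    def test_noiseless_report_matches_truth(self, fixture_dir):
        outdir, cfg = fixture_dir
        cfg.input_dir = str(outdir)
        report = cmd_measure(cfg)
        assert (report["status"] == "ok").all()
        for _, row in report.iterrows():
            truth = json.loads(
                (outdir / f"{row.egg_id}_truth.json").read_text()
            )
            assert row.spot_number == truth["n_spots"]
            assert row.spottiness == pytest.approx(
                truth["spottiness_truth"], abs=1.0
            )
            assert row.b_vis == pytest.approx(
                np.mean([truth["background_reflectance"][b]
                         for b in "RGB"]), abs=0.5,
            )
            assert row.b_uv == pytest.approx(
                truth["background_reflectance"]["UV"], abs=1.0
            )
            assert row.volume_mm3 == pytest.approx(
                truth["volume_mm3"], rel=0.02
            )

    def test_too_few_control_points_flags_row(self, fixture_dir, tmp_path):
        outdir, cfg = fixture_dir
        import shutil

        clone = tmp_path / "clone"
        shutil.copytree(outdir, clone)
        sc = clone / "egg000_truth.json"
        truth = json.loads(sc.read_text())
        truth["control_points_vis"] = truth["control_points_vis"][:5]
        truth["control_points_uv"] = truth["control_points_uv"][:5]
        sc.write_text(json.dumps(truth))
        cfg2 = RunConfig(seed=4, input_dir=str(clone),
                         output_dir=str(tmp_path / "rep"))
        report = cmd_measure(cfg2).set_index("egg_id")
        assert report.loc["egg000", "status"] == "too_few_control_points"
        assert np.isnan(report.loc["egg000", "b_uv"])
        assert report.loc["egg000", "spot_number"] > 0  # VIS side still ran

    def test_empty_input_dir_gives_empty_report(self, tmp_path):
        empty = tmp_path / "none"
        empty.mkdir()
        cfg = RunConfig(seed=1, input_dir=str(empty),
                        output_dir=str(tmp_path / "out"))
        report = cmd_measure(cfg)
        assert len(report) == 0
        assert "spottiness" in report.columns


class TestAnalyze:
    def test_selection_tables_written(self, tmp_path):
        table = eggsim.make_trait_dataset(seed=6).table
        csv = tmp_path / "traits.csv"
        table.to_csv(csv, index=False)
        cfg = RunConfig(seed=6, trait_csv=str(csv),
                        output_dir=str(tmp_path / "out"))
        results = cmd_analyze(cfg)
        st = pd.read_csv(tmp_path / "out" / "pc1_spatio_temporal.csv")
        assert set(st["model"]) == {
            "Year + s(latitude)", "Year + latitude", "Latitude", "Year",
            "Null model",
        }
        for resp in ("pc1", "pc2"):
            for key in ("spatio_temporal", "environmental"):
                w = results[resp][key].table["weight"]
                assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_missing_columns_named(self, tmp_path):
        csv = tmp_path / "bad.csv"
        pd.DataFrame({"site": ["a"], "pc1": [0.1]}).to_csv(csv, index=False)
        cfg = RunConfig(seed=1, trait_csv=str(csv),
                        output_dir=str(tmp_path / "out"))
        with pytest.raises(KeyError, match="latitude"):
            cmd_analyze(cfg)


class TestCLI:
    def test_simulate_and_analyze_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from ovoscope.cli import main

        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            yaml.safe_dump(
                dict(seed=3, n_eggs=0, output_dir=str(tmp_path / "sim"))
            )
        )
        res = runner.invoke(main, ["simulate", "--config", str(cfg)])
        assert res.exit_code == 0, res.output

        cfg2 = tmp_path / "cfg2.yaml"
        cfg2.write_text(
            yaml.safe_dump(
                dict(
                    seed=3,
                    trait_csv=str(tmp_path / "sim" / "traits_truth.csv"),
                    output_dir=str(tmp_path / "ana"),
                )
            )
        )
        res = runner.invoke(main, ["analyze", "--config", str(cfg2)])
        assert res.exit_code == 0, res.output
        assert "best spatio-temporal model" in res.output
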