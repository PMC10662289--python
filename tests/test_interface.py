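"""CSV schemas, configuration, and the command-line pipeline."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pollenlra import io
from pollenlra.cli import main


class TestPollenIO:
    def test_round_trip(self, tmp_path, small_scenario):
        path = tmp_path / "counts.csv"
        io.write_pollen(small_scenario.data.pollen, path)
        back = io.read_pollen(path)
        pd.testing.assert_frame_equal(
            back, small_scenario.data.pollen, check_like=True
        )

    def test_missing_pair_filled_with_zero(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("site,taxon,count\ns1,A,5\ns1,B,3\ns2,A,7\n")
        got = io.read_pollen(path)
        assert got.loc["s2", "B"] == 0
        assert got.shape == (2, 2)

    def test_fractional_count_rejected_with_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("site,taxon,count\ns1,A,5\ns1,B,3.5\n")
        with pytest.raises(ValueError, match="row 3"):
            io.read_pollen(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("site,taxon,count\ns1,A,-2\n")
        with pytest.raises(ValueError, match="row 2"):
            io.read_pollen(path)


class TestRingsIO:
    def test_round_trip(self, tmp_path, small_scenario):
        path = tmp_path / "rings.csv"
        io.write_rings(small_scenario.data.veg, path)
        back = io.read_rings(path)
        for site, rv in small_scenario.data.veg.items():
            np.testing.assert_allclose(back[site].ring_bounds, rv.ring_bounds)
            pd.testing.assert_frame_equal(
                back[site].cover.sort_index(), rv.cover.sort_index(),
                check_like=True,
            )

    def test_zone_style_rings_accepted(self, tmp_path):
        path = tmp_path / "r.csv"
        rows = ["site,ring_start_m,ring_end_m,taxon,cover_pct"]
        for z1, z2 in [(0.5, 10.5), (10.5, 100.0), (100.0, 1500.0)]:
            rows.append(f"s1,{z1},{z2},Poaceae,40")
        path.write_text("\n".join(rows) + "\n")
        got = io.read_rings(path)
        assert got["s1"].ring_bounds[0] == 0.5
        assert got["s1"].extent == 1500.0

    def test_survey_starting_at_zero_clipped_to_basin_edge(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,ring_start_m,ring_end_m,taxon,cover_pct\n"
            "s1,0,10.5,Poaceae,40\ns1,10.5,100,Poaceae,20\n"
        )
        got = io.read_rings(path)
        assert got["s1"].ring_bounds[0] == 0.5

    def test_overlapping_rings_rejected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,ring_start_m,ring_end_m,taxon,cover_pct\n"
            "s1,0.5,50,Poaceae,40\ns1,40,100,Poaceae,20\n"
        )
        with pytest.raises(ValueError, match="s1.*overlapping"):
            io.read_rings(path)

    def test_gapped_rings_rejected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,ring_start_m,ring_end_m,taxon,cover_pct\n"
            "s1,0.5,50,Poaceae,40\ns1,60,100,Poaceae,20\n"
        )
        with pytest.raises(ValueError, match="s1.*gapped"):
            io.read_rings(path)

    def test_negative_cover_rejected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,ring_start_m,ring_end_m,taxon,cover_pct\ns1,0.5,50,Poaceae,-1\n"
        )
        with pytest.raises(ValueError, match="negative cover"):
            io.read_rings(path)


class TestOtherSchemas:
    def test_fsp_round_trip(self, tmp_path):
        fsp = pd.Series({"Pinus": 0.031, "Poaceae": 0.035})
        back = io.read_fsp(io.write_fsp(fsp, tmp_path / "fsp.csv"))
        pd.testing.assert_series_equal(back, fsp, check_names=False)

    def test_composition_and_buffers_round_trip(self, tmp_path, small_scenario):
        sc = small_scenario
        comp_back = io.read_composition(
            io.write_composition(sc.composition, tmp_path / "comp.csv")
        )
        pd.testing.assert_frame_equal(
            comp_back.table.sort_index(), sc.composition.table.sort_index(),
            check_like=True,
        )
        buf_back = io.read_buffer_areas(
            io.write_buffer_areas(sc.buffers, tmp_path / "buf.csv")
        )
        for r, b in sc.buffers.items():
            pd.testing.assert_series_equal(
                buf_back[r].areas.sort_index(), b.areas.sort_index(),
                check_names=False,
            )

    def test_species_map(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("species,pollen_taxon\nHumulus scandens,Cannabis/Humulus\n")
        assert io.read_species_map(path) == {
            "Humulus scandens": "Cannabis/Humulus"
        }

    def test_load_config(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            "reference_taxon: Poaceae\ncutoff_m: 800\nbuffers_km: [75, 100]\n"
            "custom_note: hello\n"
        )
        cfg = io.load_config(path)
        assert cfg.cutoff_m == 800
        assert cfg.buffers_km == (75.0, 100.0)
        assert cfg.extra == {"custom_note": "hello"}

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            io.read_pollen(path)


class TestCli:
    def test_help_exits_zero(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        assert "simulate" in result.output

    def test_unknown_subcommand_fails(self):
        result = CliRunner().invoke(main, ["frobnicate"])
        assert result.exit_code != 0

    def test_full_pipeline_on_simulated_scenario(self, tmp_path):
        """simulate -> fit-erv -> rsap -> reveals -> validate-split ->
        compare -> report, end to end on a small landscape."""
        runner = CliRunner()
        data = tmp_path / "data"
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "n_sites: 8\nn_subregion_a: 4\nextent: 600.0\n"
        )
        r = runner.invoke(
            main, ["simulate", "--seed", "5", "--config", str(cfg),
                   "--out", str(data)],
        )
        assert r.exit_code == 0, r.output
        for name in ["counts.csv", "rings.csv", "fsp.csv", "composition.csv",
                     "buffer_areas.csv", "groups.csv", "truth.json"]:
            assert (data / name).exists()

        fit_csv = tmp_path / "erv_fit.csv"
        r = runner.invoke(
            main,
            ["fit-erv", "--pollen", str(data / "counts.csv"),
             "--veg", str(data / "rings.csv"), "--fsp", str(data / "fsp.csv"),
             "--cutoff", "600", "--out", str(fit_csv)],
        )
        assert r.exit_code == 0, r.output
        fit = pd.read_csv(fit_csv)
        assert set(fit.columns) == {"taxon", "rpp", "sd", "background"}
        assert fit.loc[fit["taxon"] == "Poaceae", "rpp"].iloc[0] == 1.0

        curve_csv = tmp_path / "curve.csv"
        r = runner.invoke(
            main,
            ["rsap", "--pollen", str(data / "counts.csv"),
             "--veg", str(data / "rings.csv"), "--fsp", str(data / "fsp.csv"),
             "--max-distance", "600", "--step", "100", "--window", "300",
             "--out-curve", str(curve_csv)],
        )
        assert r.exit_code == 0, r.output
        assert curve_csv.exists()

        rv_csv = tmp_path / "reveals.csv"
        r = runner.invoke(
            main,
            ["reveals", "--counts", str(data / "counts.csv"),
             "--rpp", str(fit_csv), "--fsp", str(data / "fsp.csv"),
             "--out", str(rv_csv)],
        )
        assert r.exit_code == 0, r.output
        rv = pd.read_csv(rv_csv)
        assert rv["cover"].sum() == pytest.approx(1.0, abs=1e-6)

        split_dir = tmp_path / "split"
        r = runner.invoke(
            main,
            ["validate-split", "--pollen", str(data / "counts.csv"),
             "--veg", str(data / "rings.csv"), "--fsp", str(data / "fsp.csv"),
             "--groups", str(data / "groups.csv"), "--fit-group", "SW",
             "--apply-group", "NE", "--cutoff", "600",
             "--out", str(split_dir)],
        )
        assert r.exit_code == 0, r.output
        assert (split_dir / "reveals_estimate.csv").exists()

        comp_csv = tmp_path / "comparison.csv"
        r = runner.invoke(
            main,
            ["compare", "--counts", str(data / "counts.csv"),
             "--rv", str(rv_csv), "--composition", str(data / "composition.csv"),
             "--buffer-areas", str(data / "buffer_areas.csv"),
             "--buffers", "75,100", "--out", str(comp_csv)],
        )
        assert r.exit_code == 0, r.output
        table = pd.read_csv(comp_csv, index_col=0)
        assert {"pp", "rv", "fold", "closest_buffer"} <= set(table.columns)

        figs = tmp_path / "figures"
        r = runner.invoke(
            main, ["report", "--comparison", str(comp_csv), "--rpp",
                   "full", str(fit_csv), "--out", str(figs)],
        )
        assert r.exit_code == 0, r.output
        assert (figs / "comparison.svg").exists()

    def test_validate_loo_command(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text("n_sites: 5\nn_subregion_a: 2\nextent: 400.0\n")
        runner.invoke(main, ["simulate", "--seed", "2", "--config", str(cfg),
                             "--out", str(data)])
        out = tmp_path / "loo"
        r = runner.invoke(
            main,
            ["validate-loo", "--pollen", str(data / "counts.csv"),
             "--veg", str(data / "rings.csv"), "--fsp", str(data / "fsp.csv"),
             "--cutoff", "400", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(out / "loo_summary.csv")
        assert len(pd.read_csv(out / "loo_rpp_runs.csv")) == 5
        assert summary["mean_rv"].sum() == pytest.approx(1.0, abs=1e-6)
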