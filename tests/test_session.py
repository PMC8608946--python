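"""End-to-end pipeline and CLI tests."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from gelmech.cli import main
from gelmech.session import (
    SessionSummary,
    build_comparison_report,
    percent_difference_truncated,
    run_aspiration_pipeline,
    run_compression_pipeline,
    run_indentation_pipeline,
)
from gelmech.synthetic import (
    simulate_aspiration_session,
    simulate_compression_curve,
    simulate_indentation_session,
)


def _indentation_frame(session, indenter):
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in session.measurements],
            "sphere_label": indenter.label,
            "sphere_mass_mg": indenter.mass_mg,
            "sphere_radius_mm": indenter.radius_mm,
            "overload_mass_mg": indenter.overload_mass_mg,
            "delta_mm": [m.delta_mm for m in session.measurements],
            "h_mm": [m.gel.height_mm for m in session.measurements],
            "D_mm": [m.gel.diameter_mm for m in session.measurements],
        }
    )


class TestIndentationPipeline:
    def test_ten_repeat_session_summary(self, steel_sphere, gel):
        sess = simulate_indentation_session(
            11.86, steel_sphere, gel, n_repeats=10, noise_sd=0.03, seed=0,
            sample_id="PAA5",
        )
        summaries, records, failures = run_indentation_pipeline(
            _indentation_frame(sess, steel_sphere)
        )
        assert not failures
        assert len(records) == 10
        s = summaries["PAA5"]
        assert s.n == 10
        assert s.E_sd_kpa > 0
        assert s.E_mean_kpa == pytest.approx(11.86, rel=0.05)
        # all four model columns present per row
        for col in ("E_H_kpa", "E_H_fh_kpa", "E_NH_fh_kpa", "E_NH_fdh_kpa"):
            assert records[col].gt(0).all()

    def test_single_row_flags_small_n(self, steel_sphere, gel):
        sess = simulate_indentation_session(
            5.0, steel_sphere, gel, n_repeats=1, noise_sd=0.0, seed=0, sample_id="x"
        )
        summaries, _, _ = run_indentation_pipeline(
            _indentation_frame(sess, steel_sphere)
        )
        assert summaries["x"].n == 1
        assert "small_n" in summaries["x"].warnings

    def test_bad_rows_fail_soft(self, steel_sphere, gel):
        sess = simulate_indentation_session(
            5.0, steel_sphere, gel, n_repeats=3, noise_sd=0.0, seed=0, sample_id="x"
        )
        df = _indentation_frame(sess, steel_sphere)
        df.loc[1, "delta_mm"] = -1.0  # invalid depth
        summaries, records, failures = run_indentation_pipeline(df)
        assert len(records) == 2
        assert len(failures) == 1 and failures[0]["row"] == 1

    def test_image_rows_resolved(self, gel, tmp_path):
        import imageio.v3 as iio

        from gelmech.indentation import IndenterSpec
        from gelmech.synthetic import render_indentation_scene

        indenter = IndenterSpec("SS2.0", 261.4, 2.0)
        scene = render_indentation_scene(2.0, indenter, gel, seed=0)
        iio.imwrite(tmp_path / "scene.png", scene.image)
        df = pd.DataFrame(
            [
                {
                    "sample_id": "img",
                    "sphere_label": indenter.label,
                    "sphere_mass_mg": indenter.mass_mg,
                    "sphere_radius_mm": indenter.radius_mm,
                    "delta_mm": np.nan,
                    "h_mm": np.nan,
                    "D_mm": np.nan,
                    "image_path": "scene.png",
                }
            ]
        )
        summaries, records, failures = run_indentation_pipeline(df, image_dir=tmp_path)
        assert not failures
        assert summaries["img"].E_mean_kpa == pytest.approx(2.0, rel=0.05)


class TestAspirationPipeline:
    def test_pressure_sweep_summary(self, pipette):
        sess = simulate_aspiration_session(
            8.09, -np.linspace(3.84, 9.93, 10), pipette, noise_sd=0.05, seed=1,
            sample_id="PAA5",
        )
        df = pd.DataFrame(
            {
                "sample_id": "PAA5",
                "pressure_kpa": [m.pressure_kpa for m in sess.measurements],
                "length_mm": [m.length_mm for m in sess.measurements],
            }
        )
        summaries, details, failures = run_aspiration_pipeline(df, pipette)
        assert not failures
        assert summaries["PAA5"].E_mean_kpa == pytest.approx(8.09, rel=0.10)
        assert details["PAA5"].l_over_a_min < details["PAA5"].l_over_a_max

    def test_sign_convention_invariance(self, pipette):
        base = pd.DataFrame(
            {"sample_id": "s", "pressure_kpa": [-2.0, -4.0], "length_mm": [0.15, 0.25]}
        )
        flipped = base.assign(pressure_kpa=base.pressure_kpa.abs())
        s1, _, _ = run_aspiration_pipeline(base, pipette)
        s2, _, _ = run_aspiration_pipeline(flipped, pipette)
        assert s1["s"].E_mean_kpa == s2["s"].E_mean_kpa

    def test_low_aspiration_rows_warn(self, pipette):
        df = pd.DataFrame(
            {"sample_id": "s", "pressure_kpa": [-1.0, -1.2], "length_mm": [0.05, 0.06]}
        )
        summaries, _, _ = run_aspiration_pipeline(df, pipette)
        assert "low_aspiration" in summaries["s"].warnings


class TestCompressionPipeline:
    def test_neo_hookean_curve_identified(self):
        curve = simulate_compression_curve(10.0, noise_sd=0.0, sample_id="c1")
        df = pd.DataFrame(
            {"sample_id": "c1", "strain": curve.strain, "stress_kpa": curve.stress_kpa}
        )
        summaries, comparisons, failures = run_compression_pipeline(df)
        assert not failures
        assert comparisons["c1"]["preferred"] == "neo_hookean"
        assert summaries["c1"].E_mean_kpa == pytest.approx(10.0, rel=1e-9)


class TestComparisonReport:
    def _summary(self, sid, method, E):
        return SessionSummary(sid, method, 10, E, 0.1, ())

    def test_identical_methods_ratio_one(self):
        rep = build_comparison_report(
            [self._summary("s", "macroindentation", 5.0), self._summary("s", "aspiration", 5.0)]
        )
        assert rep.ratios.loc["s", "max_min_ratio"] == pytest.approx(1.0)
        assert not rep.ratios.loc["s", "flag"]

    def test_stiff_gel_cross_method_spread_unflagged(self):
        # the stiffest reference gel: four methods within a 1.5x band
        rep = build_comparison_report(
            [
                self._summary("PAA6", "macroindentation", 56.37),
                self._summary("PAA6", "aspiration", 39.94),
            ],
            external={"PAA6": {"afm": 40.40, "rheometry": 59.05}},
        )
        ratio = rep.ratios.loc["PAA6", "max_min_ratio"]
        assert ratio < 1.5
        assert not rep.ratios.loc["PAA6", "flag"]

    def test_ratio_invariant_to_order(self):
        a = [
            self._summary("s", "macroindentation", 2.0),
            self._summary("s", "aspiration", 7.0),
        ]
        r1 = build_comparison_report(a).ratios.loc["s", "max_min_ratio"]
        r2 = build_comparison_report(a[::-1]).ratios.loc["s", "max_min_ratio"]
        assert r1 == r2
        assert build_comparison_report(a).ratios.loc["s", "flag"]  # 3.5x spread

    def test_truncated_percent_convention(self):
        assert percent_difference_truncated(0.14, 0.13) == 7
        assert percent_difference_truncated(1.20, 1.15) == 4
        assert percent_difference_truncated(2.27, 2.27) == 0


class TestCli:
    def test_indent_command_deterministic(self, steel_sphere, gel, tmp_path):
        sess = simulate_indentation_session(
            5.0, steel_sphere, gel, n_repeats=5, noise_sd=0.02, seed=0, sample_id="g1"
        )
        csv = tmp_path / "indent.csv"
        _indentation_frame(sess, steel_sphere).to_csv(csv, index=False)
        runner = CliRunner()
        outs = []
        for d in ("o1", "o2"):
            result = runner.invoke(
                main, ["indent", "--csv", str(csv), "--out-dir", str(tmp_path / d)]
            )
            assert result.exit_code == 0, result.output
            outs.append((tmp_path / d / "indentation_summary.json").read_text())
            assert "g1" in result.output
        assert outs[0] == outs[1]
        payload = json.loads(outs[0])
        assert payload["provenance"]["tool"] == "gelmech"
        assert payload["summaries"]["g1"]["n"] == 5

    def test_aspirate_command(self, pipette, tmp_path):
        sess = simulate_aspiration_session(
            8.0, [-2.0, -4.0, -6.0], pipette, noise_sd=0.0, seed=0, sample_id="g1"
        )
        csv = tmp_path / "asp.csv"
        pd.DataFrame(
            {
                "sample_id": "g1",
                "pressure_kpa": [m.pressure_kpa for m in sess.measurements],
                "length_mm": [m.length_mm for m in sess.measurements],
            }
        ).to_csv(csv, index=False)
        runner = CliRunner()
        result = runner.invoke(
            main, ["aspirate", "--csv", str(csv), "--out-dir", str(tmp_path / "out")]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "out" / "aspiration_summary.json").read_text())
        assert payload["summaries"]["g1"]["E_mean_kpa"] == pytest.approx(8.0, rel=1e-6)

    def test_simulate_and_report_round_trip(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "simulate", "--kind", "compression", "--e-kpa", "6", "--n", "2",
                "--seed", "3", "--out-dir", str(tmp_path / "fx"),
            ],
        )
        assert result.exit_code == 0, result.output
        manifest = json.loads((tmp_path / "fx" / "manifest.json").read_text())
        assert len(manifest["items"]) == 2
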