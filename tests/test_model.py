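"""Model/Results front end and the command-line interface.

End-to-end fits here run on deliberately small datasets (2 joints, 2-3
swings per group, short clips) — enough to exercise every stage without
the cost of a full study-sized run.
"""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from swinghht.cli import main
from swinghht.model import AnalysisConfig, SwingAnalysis
from swinghht.synthetic import default_recipe, make_dataset, render


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("ds")
    make_dataset(
        d,
        n_per_group=2,
        groups=("straight", "slice_head_up"),
        seed=13,
        frame_bounds=(150, 160),
        impact_bounds=(85, 95),
    )
    return d


@pytest.fixture(scope="module")
def fitted(small_dataset):
    model = SwingAnalysis.from_dataset(
        small_dataset, joints=["Neck", "LeftArm"]
    )
    return model.fit()


class TestSwingAnalysis:
    def test_fit_builds_one_ensemble_per_label(self, fitted):
        assert sorted(fitted.labels) == ["slice_head_up", "straight"]
        for label in fitted.labels:
            ens = fitted.ensembles[label]
            assert ens.n_members == 2
            assert set(ens.averaged) == {"Neck", "LeftArm"}

    def test_members_are_impact_aligned(self, fitted):
        for ens in fitted.ensembles.values():
            for sw in ens.members:
                for js in sw.values():
                    assert js.impact_index == ens.pre
                    assert js.n_samples == ens.window_length

    def test_frequency_stats_shape_and_cv(self, fitted):
        stats = fitted.frequency_stats("straight", "Neck")
        assert {"mean_hz", "sd_hz", "cv"} <= set(stats.columns)
        defined = stats.dropna(subset=["cv"])
        np.testing.assert_allclose(
            defined["cv"], defined["sd_hz"] / defined["mean_hz"]
        )

    def test_summary_mentions_joints_and_groups(self, fitted):
        text = fitted.summary()
        for token in ("Neck", "LeftArm", "straight", "slice_head_up", "IMF"):
            assert token in text

    def test_spectrum_grid_shape(self, fitted):
        spec = fitted.spectrum("straight", "Neck")
        ens = fitted.ensembles["straight"]
        assert spec.power.shape[0] == ens.window_length
        assert spec.impact_time == 0.0

    def test_compare_reports_all_joints(self, fitted):
        report = fitted.compare("straight", "slice_head_up")
        assert sorted(report.index) == ["LeftArm", "Neck"]
        assert {"ratio", "flagged"} <= set(report.columns)

    def test_missing_impact_annotation_rejected(self):
        clip, _ = render(default_recipe(seed=1))
        clip.impact_frame = None
        with pytest.raises(ValueError, match="impact_frame"):
            SwingAnalysis([clip])

    def test_pooled_stacking_keeps_mode_alignment_across_joints(self):
        clip, _ = render(default_recipe(seed=3, duration=1.2, impact_time=0.7))
        model = SwingAnalysis(
            [clip],
            joints=["Neck", "LeftArm"],
            config=AnalysisConfig(joint_stacking="pooled"),
        )
        res = model.fit()
        ens = res.ensembles["straight"]
        n_neck = ens.averaged["Neck"].n_modes
        n_arm = ens.averaged["LeftArm"].n_modes
        assert n_neck == n_arm  # both joints came from one decomposition


class TestConfig:
    def test_yaml_and_validation(self):
        cfg = AnalysisConfig(sd_threshold=0.3, n_directions=32)
        assert cfg.resolved_directions(3) == 32
        with pytest.raises(ValueError):
            AnalysisConfig(joint_stacking="both")
        with pytest.raises(ValueError):
            AnalysisConfig(sd_threshold=-1)


class TestCLI:
    def test_synth_writes_dataset(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ds"
        res = runner.invoke(
            main, ["synth", "--out", str(out), "--n", "1", "--groups", "straight", "--seed", "2"]
        )
        assert res.exit_code == 0, res.output
        assert (out / "swings.csv").exists()
        assert len(list(out.glob("*.bvh"))) == 1

    def test_synth_seed_reproducible(self, tmp_path):
        runner = CliRunner()
        for sub in ("a", "b"):
            res = runner.invoke(
                main,
                ["synth", "--out", str(tmp_path / sub), "--n", "1",
                 "--groups", "straight", "--seed", "5"],
            )
            assert res.exit_code == 0
        assert (tmp_path / "a" / "straight_00.bvh").read_text() == (
            tmp_path / "b" / "straight_00.bvh"
        ).read_text()

    def test_synth_bad_group_lists_valid_ones(self, tmp_path):
        res = CliRunner().invoke(main, ["synth", "--out", str(tmp_path), "--groups", "hook"])
        assert res.exit_code != 0
        assert "straight" in res.output

    def test_analyze_writes_report_and_manifest(self, small_dataset, tmp_path):
        out = tmp_path / "report"
        res = CliRunner().invoke(
            main,
            [
                "analyze", "--bvh-dir", str(small_dataset), "--out", str(out),
                "--joints", "Neck,LeftArm", "--no-plots",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (out / "manifest.yaml").exists()
        assert (out / "sync_summary.csv").exists()
        assert (out / "excess_slice_head_up_vs_straight.csv").exists()
        assert (out / "spectrum_straight_Neck.csv").exists()

    def test_analyze_rerun_reproduces_outputs(self, small_dataset, tmp_path):
        args = lambda out: [
            "analyze", "--bvh-dir", str(small_dataset), "--out", str(out),
            "--joints", "Neck", "--no-plots",
        ]
        runner = CliRunner()
        assert runner.invoke(main, args(tmp_path / "r1")).exit_code == 0
        assert runner.invoke(main, args(tmp_path / "r2")).exit_code == 0
        for name in ("sync_summary.csv", "spectrum_straight_Neck.csv"):
            assert (tmp_path / "r1" / name).read_text() == (
                tmp_path / "r2" / name
            ).read_text()

    def test_empty_input_dir_is_data_error_without_partial_report(self, tmp_path):
        out = tmp_path / "report"
        res = CliRunner().invoke(
            main, ["analyze", "--bvh-dir", str(tmp_path), "--out", str(out)]
        )
        assert res.exit_code == 3
        assert not out.exists()

    def test_stats_prints_table(self, small_dataset):
        res = CliRunner().invoke(
            main,
            ["stats", "--bvh-dir", str(small_dataset), "--joints", "Neck,LeftArm"],
        )
        assert res.exit_code == 0, res.output
        assert "IMF" in res.output and "cv" in res.output
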