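"""File round-trips, configuration, the end-to-end runners and the CLI."""

import json
from dataclasses import replace

import numpy as np
import pytest
from click.testing import CliRunner

from ftcdli.cli import main as cli_main
from ftcdli.io import load_config, read_recording, write_recording
from ftcdli.pipeline import run_group, run_subject
from ftcdli.preprocess import PipelineConfig
from ftcdli.simulate import CohortSpec, SimParams, simulate_cohort, simulate_recording


@pytest.fixture(scope="module")
def small_recording():
    return simulate_recording(SimParams(n_trials=4, seed=21), subject_id="io01")


class TestRecordingFiles:
    def test_round_trip_is_bit_identical(self, small_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(small_recording, path)
        back = read_recording(path)
        assert back.subject_id == small_recording.subject_id
        assert back.sampling_rate == small_recording.sampling_rate
        assert np.array_equal(back.time, small_recording.time)
        assert np.array_equal(back.left, small_recording.left)
        assert np.array_equal(back.right, small_recording.right)
        assert back.triggers == small_recording.triggers

    def test_marker_column_defines_triggers(self, small_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(small_recording, path)
        text = path.read_text()
        assert text.count(",1\n") == len(small_recording.triggers)

    def test_non_monotone_time_error_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# subject_id: x\n"
            "time,left,right,marker\n"
            "0.0,60,60,1\n"
            "0.01,60,60,0\n"
            "0.005,60,60,0\n"
        )
        with pytest.raises(ValueError, match="line"):
            read_recording(path)

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,left\n0.0,60\n0.01,61\n")
        with pytest.raises(ValueError, match="right"):
            read_recording(path)

    def test_no_triggers_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,left,right,marker\n0.0,60,60,0\n0.01,60,60,0\n")
        with pytest.raises(ValueError, match="trigger"):
            read_recording(path)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("poi: [4.0, 16.0]\nmin_accepted_trials: 7\n")
        cfg = load_config(p)
        assert cfg.poi == (4.0, 16.0)
        assert cfg.min_accepted_trials == 7
        assert cfg.baseline_window == (-10.0, -2.0)  # defaults kept

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("epoch_windw: [-12, 26]\n")
        with pytest.raises(ValueError, match="epoch_windw"):
            load_config(p)

    def test_json_supported(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"alpha": 0.01}))
        assert load_config(p).alpha == 0.01


class TestRunSubject:
    def test_same_file_twice_identical(self, small_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(small_recording, path)
        r1, _ = run_subject(path)
        r2, _ = run_subject(path)
        assert r1.li == r2.li
        assert r1.peak_latency == r2.peak_latency
        assert r1.per_trial_li.tolist() == r2.per_trial_li.tolist()

    def test_excluded_when_too_few_trials_survive(self):
        rec = simulate_recording(SimParams(n_trials=25, seed=23))
        # 17 of 25 trials rejected behaviourally leaves 8 < 9
        result, _ = run_subject(rec, behavioral_rejects=range(17))
        assert result.n_accepted == 8
        assert result.excluded

    def test_null_subject_is_low_lateralised(self):
        """A subject with no true asymmetry is classified low ~ (1 - alpha)."""
        count_low = 0
        for seed in range(100):
            p = SimParams(true_li=0.0, noise_sd=0.5, seed=seed)
            res, _ = run_subject(simulate_recording(p))
            count_low += res.category == "low"
        assert count_low >= 90


class TestRunGroup:
    def test_identical_groups_compare_as_null(self, tmp_path):
        base = SimParams(n_trials=12, noise_sd=0.5)
        spec = CohortSpec(n_subjects=4, li_mean=2.5, li_sd=1.0,
                          base_params=base, seed=31)
        recs, _ = simulate_cohort(spec)
        report = run_group(recs, recs, equivalence_bound=10.0)
        assert report["comparisons"]["li"]["t"] == pytest.approx(0.0, abs=1e-12)
        if "categories" in report["comparisons"]:
            assert report["comparisons"]["categories"]["chi2"] == pytest.approx(0.0)
        assert report["equivalence"]["verdict_equivalent"]
        assert report["group_a"]["n"] == 4

    def test_report_covers_standard_rows(self, tmp_path):
        spec = CohortSpec(
            n_subjects=4, li_mean=2.0, li_sd=1.5,
            base_params=SimParams(n_trials=10, noise_sd=0.5), seed=33,
        )
        recs, _ = simulate_cohort(spec)
        report = run_group(recs, recs)
        for key in ("n", "li_mean", "li_sd", "n_trials_mean", "peak_latency_mean",
                    "category_counts", "category_percent", "split_half_r",
                    "subjects"):
            assert key in report["group_a"]
        for key in ("li", "n_trials", "peak_latency", "reliability"):
            assert key in report["comparisons"]
        assert report["config_hash"]


class TestCli:
    def test_handedness_subcommand(self):
        res = CliRunner().invoke(cli_main, ["handedness", "--counts", "5", "3", "2"])
        assert res.exit_code == 0
        assert json.loads(res.output)["lq"] == 20.0

    def test_bayes_subcommand(self):
        res = CliRunner().invoke(
            cli_main,
            ["bayes", "--diff", "-0.44", "--se", "0.98", "--prior-sd", "0.5"],
        )
        assert res.exit_code == 0
        assert 0.70 < json.loads(res.output)["bf"] < 0.80

    def test_equivalence_subcommand_with_derived_bound(self):
        res = CliRunner().invoke(
            cli_main,
            [
                "equivalence",
                "--mean1", "1.79", "--sd1", "2.95", "--n1", "19",
                "--mean2", "2.23", "--sd2", "3.02", "--n2", "19",
                "--derive-bound", "0.05", "38", "20", "20", "2.985",
            ],
        )
        assert res.exit_code == 0
        out = json.loads(res.output)
        assert out["sesoi_derivation"]["bound"] == pytest.approx(1.9, abs=0.05)
        assert out["verdict_reject_upper"] and not out["verdict_reject_lower"]

    def test_simulate_then_subject(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "cohort"
        res = runner.invoke(
            cli_main,
            ["simulate", "--subjects", "1", "--li-mean", "3.0", "--trials", "10",
             "--seed", "5", "--out", str(out_dir)],
        )
        assert res.exit_code == 0
        files = sorted(out_dir.glob("S*.csv"))
        assert len(files) == 1
        assert (out_dir / "ground_truth.json").exists()
        res2 = runner.invoke(cli_main, ["subject", str(files[0])])
        assert res2.exit_code == 0
        payload = json.loads(res2.output)
        # 10 trials with trial-to-trial LI jitter: subject LI within ~2 SD
        assert payload["li"] == pytest.approx(3.0, abs=2.0)
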