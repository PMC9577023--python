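"""Tests for the experiment harness: configs, records, reproducibility."""

import json
import numpy as np
import pytest

from fbmdrop import (
    ExperimentConfig,
    ImageData,
    compare_conditions,
    make_regression_data,
    make_synthetic_glyphs,
    mnist_config,
    regression_config,
    run_experiment,
)


def tiny_regression_config(mode="none", **overrides):
    return regression_config(
        mode=mode,
        epochs=3,
        n_fibers=4 if mode == "fbm" else None,
        **overrides,
    )


@pytest.fixture(scope="module")
def reg_data():
    return (
        make_regression_data(50, 0.3, seed=100),
        make_regression_data(50, 0.3, seed=101),
    )


class TestConfigValidation:
    def test_benchmark_presets(self):
        reg = regression_config("fbm")
        assert reg.layer_sizes == (1, 100, 100, 1)
        assert reg.grid_sides == (10, 10)
        assert reg.n_fibers == 12
        mn = mnist_config("fbm")
        assert mn.layer_sizes == (784, 1024, 1024, 10)
        assert mn.grid_sides == (32, 32)
        assert mn.n_fibers == 60

    def test_non_square_hidden_width_rejected_for_dropout(self):
        with pytest.raises(ValueError, match="square"):
            ExperimentConfig(
                task="regression", layer_sizes=(1, 99, 99, 1), mode="fbm"
            )

    def test_non_square_width_allowed_without_dropout(self):
        ExperimentConfig(task="regression", layer_sizes=(1, 99, 99, 1), mode="none")

    def test_empty_training_set_rejected(self):
        cfg = tiny_regression_config()
        with pytest.raises(ValueError):
            cfg.iters_per_epoch(0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ExperimentConfig(
                task="regression", layer_sizes=(1, 100, 100, 1), mode="fancy"
            )

    def test_dataset_width_mismatch_rejected(self):
        cfg = ExperimentConfig(
            task="classification",
            layer_sizes=(100, 16, 16, 10),
            mode="none",
            epochs=1,
        )
        glyphs = make_synthetic_glyphs(2, seed=0)
        with pytest.raises(ValueError, match="width"):
            run_experiment(cfg, glyphs, glyphs)


class TestRunRecord:
    def test_gap_is_test_minus_train_exactly(self, reg_data):
        rec = run_experiment(tiny_regression_config(), *reg_data)
        assert np.array_equal(rec.gap, rec.test_loss - rec.train_loss)
        assert rec.final_gap == rec.gap[-1]

    def test_record_lengths_match_epochs(self, reg_data):
        rec = run_experiment(tiny_regression_config(), *reg_data)
        assert rec.train_loss.shape == rec.test_loss.shape == (3,)
        assert rec.test_accuracy is None

    def test_full_reproducibility_under_fixed_seed(self, reg_data):
        for mode in ("none", "standard", "fbm"):
            a = run_experiment(tiny_regression_config(mode, seed=5), *reg_data)
            b = run_experiment(tiny_regression_config(mode, seed=5), *reg_data)
            assert np.array_equal(a.train_loss, b.train_loss)
            assert np.array_equal(a.test_loss, b.test_loss)

    def test_fbm_run_reports_rate_and_fiber_count(self, reg_data):
        rec = run_experiment(tiny_regression_config("fbm"), *reg_data)
        assert rec.n_fibers_used == 4
        assert 0.0 < rec.mean_drop_rate < 0.5

    def test_csv_and_json_export(self, tmp_path, reg_data):
        rec = run_experiment(tiny_regression_config("standard"), *reg_data)
        frame = rec.to_dataframe()
        assert list(frame.columns) == [
            "epoch", "condition", "train_loss", "test_loss", "gap",
        ]
        rec.to_json(tmp_path / "run.json")
        loaded = json.loads((tmp_path / "run.json").read_text())
        assert loaded["condition"] == "standard"
        assert loaded["final_gap"] == pytest.approx(rec.final_gap)


class TestClassificationRun:
    def test_glyph_training_reaches_high_accuracy_without_dropout(self):
        """The fixture is learnable: a small net exceeds 90% test accuracy."""
        full = make_synthetic_glyphs(40, seed=11)
        train = ImageData(full.images[:200], full.labels[:200], full.source)
        test = ImageData(full.images[200:], full.labels[200:], full.source)
        cfg = ExperimentConfig(
            task="classification",
            layer_sizes=(784, 144, 144, 10),
            mode="none",
            lr=0.001,
            epochs=20,
            batch_size=10,
            seed=0,
        )
        rec = run_experiment(cfg, train, test)
        assert rec.test_accuracy[-1] > 0.90

    def test_accuracy_recorded_per_epoch(self):
        full = make_synthetic_glyphs(4, seed=12)
        data = ImageData(full.images, full.labels, full.source)
        cfg = ExperimentConfig(
            task="classification",
            layer_sizes=(784, 16, 16, 10),
            mode="none",
            epochs=2,
            batch_size=8,
            lr=0.001,
        )
        rec = run_experiment(cfg, data, data)
        assert rec.test_accuracy.shape == (2,)


class TestCompareConditions:
    def test_identical_seeds_give_identical_trajectories(self, reg_data):
        base = tiny_regression_config("fbm")
        a = compare_conditions(base, *reg_data, n_seeds=2)
        b = compare_conditions(base, *reg_data, n_seeds=2)
        for mode in a.records:
            for ra, rb in zip(a.records[mode], b.records[mode]):
                assert np.array_equal(ra.train_loss, rb.train_loss)

    def test_summary_and_exports(self, tmp_path, reg_data):
        base = tiny_regression_config("fbm")
        res = compare_conditions(base, *reg_data, n_seeds=2)
        summ = res.summary()
        assert set(summ) == {"none", "standard", "fbm"}
        assert summ["fbm"]["n_runs"] == 2
        res.to_csv(tmp_path / "curves.csv")
        res.to_json(tmp_path / "summary.json")
        assert (tmp_path / "curves.csv").exists()
        assert json.loads((tmp_path / "summary.json").read_text())

    def test_fbm_dropout_not_inferior_to_no_dropout_on_glyphs(self):
        """Scaled-down classification: fiber dropout generalizes at least as
        well as no dropout, within Monte-Carlo uncertainty of the mean final
        testing loss."""
        full = make_synthetic_glyphs(35, seed=42, noise_sd=0.35)
        train = ImageData(full.images[:50], full.labels[:50], full.source)
        test = ImageData(full.images[50:], full.labels[50:], full.source)
        finals = {}
        for mode in ("none", "fbm"):
            losses = []
            for s in range(4):
                cfg = ExperimentConfig(
                    task="classification",
                    layer_sizes=(784, 144, 144, 10),
                    mode=mode,
                    lr=0.001,
                    epochs=40,
                    batch_size=10,
                    seed=s,
                )
                losses.append(run_experiment(cfg, train, test).test_loss[-1])
            finals[mode] = np.array(losses)
        diff = finals["fbm"].mean() - finals["none"].mean()
        se = np.sqrt(
            finals["fbm"].var(ddof=1) / 4 + finals["none"].var(ddof=1) / 4
        )
        assert diff <= 2.0 * se
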