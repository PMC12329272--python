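"""Split logic, the seeded training loop, and the benchmark orchestrator."""

import numpy as np
import pandas as pd
import pytest

from unetbench import (
    TrainConfig,
    VariantSpec,
    build_unet,
    closed_form_param_count,
    generate_phantom,
    run_benchmark,
    split_dataset,
    train_model,
)
from unetbench.experiment import evaluate_model


def _manifest(class_sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for cls, n in class_sizes.items():
        rows += [{"identifier": f"{cls}-{i}", "class_label": cls} for i in range(n)]
    return pd.DataFrame(rows)


class TestTrainConfig:
    def test_full_scale_defaults(self):
        cfg = TrainConfig()
        assert cfg.image_size == (256, 256)
        assert cfg.epochs == 10
        assert cfg.batch_size == 20
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.split_fraction == 0.8

    @pytest.mark.parametrize("kwargs", [
        {"epochs": 0},
        {"batch_size": 0},
        {"learning_rate": 0.0},
        {"split_fraction": 1.0},
        {"optimizer": "sgd"},
    ])
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)

    def test_config_roundtrip(self):
        cfg = TrainConfig(image_size=(64, 64), epochs=3)
        assert TrainConfig.from_config(cfg.to_config()) == cfg


class TestSplit:
    def test_basic_80_20(self):
        train, test = split_dataset(_manifest({"A": 100}), 0.8, seed=0,
                                    stratify=False)
        assert (len(train), len(test)) == (80, 20)

    def test_three_class_dataset_arithmetic(self):
        """The three-class radiograph dataset splits 3108/778 at 0.8."""
        manifest = _manifest({"COVID": 1200, "Normal": 1341,
                              "Viral Pneumonia": 1345})
        for stratify in (False, True):
            train, test = split_dataset(manifest, 0.8, seed=1, stratify=stratify)
            assert (len(train), len(test)) == (3108, 778)

    def test_partition_is_disjoint_and_exhaustive(self):
        manifest = _manifest({"A": 37, "B": 23})
        train, test = split_dataset(manifest, 0.7, seed=3)
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(manifest["identifier"])

    def test_stratified_preserves_class_balance(self):
        manifest = _manifest({"A": 50, "B": 100})
        train, _ = split_dataset(manifest, 0.8, seed=0, stratify=True)
        a = sum(i.startswith("A-") for i in train)
        assert (a, len(train) - a) == (40, 80)

    def test_seeded_reproducibility(self):
        manifest = _manifest({"A": 60})
        assert split_dataset(manifest, 0.8, seed=9) == \
            split_dataset(manifest, 0.8, seed=9)
        assert split_dataset(manifest, 0.8, seed=9) != \
            split_dataset(manifest, 0.8, seed=10)

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_manifest({"A": 10, "B": 1}), 0.8, seed=0, stratify=True)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(pd.DataFrame(columns=["identifier"]), 0.8, seed=0)


def _easy_pairs(n, size=32, seed=11):
    from dataclasses import replace

    from unetbench import PhantomParams
    params = PhantomParams(size=(size, size), noise_sigma=0.0, rib_amplitude=0.0,
                           background_level=0.85, lung_contrast=0.55)
    return [generate_phantom(replace(params, seed=seed + i), identifier=f"p{i}")
            for i in range(n)]


class TestTraining:
    def test_loss_decreases_on_easy_phantoms(self, small_spec):
        pairs = _easy_pairs(30)
        cfg = TrainConfig(image_size=(32, 32), epochs=3, batch_size=10,
                          learning_rate=1e-3, seed=0)
        model = build_unet(small_spec, seed=cfg.seed)
        record = train_model(model, pairs, cfg)
        assert len(record.loss_history) == 3
        assert record.loss_history[-1] < record.loss_history[0]
        assert record.parameter_count == closed_form_param_count(small_spec)

    def test_identical_seeds_identical_history(self, small_spec):
        pairs = _easy_pairs(20)
        cfg = TrainConfig(image_size=(32, 32), epochs=2, batch_size=10,
                          learning_rate=1e-3, seed=4)
        h1 = train_model(build_unet(small_spec, seed=4), pairs, cfg).loss_history
        h2 = train_model(build_unet(small_spec, seed=4), pairs, cfg).loss_history
        assert h1 == h2

    def test_empty_training_set_rejected(self, small_spec):
        with pytest.raises(ValueError):
            train_model(build_unet(small_spec), [], TrainConfig())

    def test_evaluate_model_reports_per_image(self, small_spec):
        pairs = _easy_pairs(4)
        rep = evaluate_model(build_unet(small_spec, seed=0), pairs)
        assert len(rep.per_image) == 4
        assert 0.0 <= rep.micro_dice <= 1.0


class TestRunBenchmark:
    @pytest.fixture()
    def bench(self, tmp_path, tiny_dataset):
        root, _ = tiny_dataset
        spec = VariantSpec(name="small8", encoder_levels=2, width_mode="fixed",
                           fixed_filters=8)
        cfg = TrainConfig(image_size=(32, 32), epochs=2, batch_size=6,
                          learning_rate=1e-3, seed=0)
        out = tmp_path / "out"
        records = run_benchmark([spec], root, cfg, out, panels=2)
        return records, out, spec

    def test_reports_written(self, bench):
        records, out, spec = bench
        assert len(records) == 1
        for name in ("params_table.csv", "metrics_table.csv", "split.csv",
                     "params_table.md", "metrics_table.md"):
            assert (out / name).exists()
        assert (out / "panels" / f"{spec.name}.png").exists()
        assert (out / f"{spec.name}.weights.npz").exists()

    def test_parameter_count_matches_audit(self, bench):
        records, out, spec = bench
        table = pd.read_csv(out / "params_table.csv")
        assert table.loc[0, "total_params"] == closed_form_param_count(spec)
        assert records[0].parameter_count == closed_form_param_count(spec)

    def test_no_train_test_leakage(self, bench):
        _, out, _ = bench
        split = pd.read_csv(out / "split.csv")
        train = set(split[split["split"] == "train"]["identifier"])
        test = set(split[split["split"] == "test"]["identifier"])
        assert not train & test
        assert len(train) + len(test) == 12

    def test_metrics_table_dice_dominates_iou(self, bench):
        _, out, _ = bench
        table = pd.read_csv(out / "metrics_table.csv")
        assert (table["dice_micro"] >= table["iou_micro"]).all()
        assert (table["dice_macro"] >= table["iou_macro"]).all()

    def test_empty_variant_list_rejected(self, tmp_path, tiny_dataset):
        root, _ = tiny_dataset
        with pytest.raises(ValueError):
            run_benchmark([], root, TrainConfig(), tmp_path / "o")

    def test_end_to_end_determinism(self, tmp_path, tiny_dataset):
        root, _ = tiny_dataset
        spec = VariantSpec(name="tiny4", encoder_levels=1, width_mode="fixed",
                           fixed_filters=4)
        cfg = TrainConfig(image_size=(32, 32), epochs=1, batch_size=6,
                          learning_rate=1e-3, seed=2)
        run_benchmark([spec], root, cfg, tmp_path / "r1", panels=0)
        run_benchmark([spec], root, cfg, tmp_path / "r2", panels=0)
        t1 = (tmp_path / "r1" / "metrics_table.csv").read_text()
        t2 = (tmp_path / "r2" / "metrics_table.csv").read_text()
        assert t1 == t2
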