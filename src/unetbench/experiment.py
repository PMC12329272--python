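"""Benchmark orchestration: split, train, evaluate, report.

The full-scale protocol — 256x256 inputs, 10 epochs, batch size 20, Adam at
1e-4, pixelwise binary cross-entropy, 80/20 train/test split — is the
benchmark's reference setup, and every stage is seeded so two runs with the same seed
produce identical reports. A reduced "easy suite" protocol (64x64 noiseless
high-contrast phantoms, 5 epochs, Adam at 1e-3, batch 10) exercises the same
code path at desk scale.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import load_pairs, scan_dataset
from .metrics import MetricReport, evaluate_dataset
from .model import UNet, build_unet
from .nn.losses import bce_with_logits
from .nn.optim import Adam
from .preprocess import SegmentationPair, preprocess_pair
from .synthetic import PhantomParams
from .variants import VariantSpec, closed_form_param_count, resolve_variant

logger = logging.getLogger("unetbench")

__all__ = [
    "TrainConfig",
    "RunRecord",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "run_benchmark",
    "easy_suite_config",
    "easy_suite_params",
]


@dataclass
class TrainConfig:
    """Training protocol; defaults are the full-scale benchmark protocol."""

    image_size: tuple[int, int] = (256, 256)
    epochs: int = 10
    batch_size: int = 20
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    loss: str = "bce"
    split_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0
    device: str = "cpu"
    threshold: float = 0.5
    gaussian_kernel: int = 3
    gaussian_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.loss.lower() not in ("bce", "binarycrossentropy"):
            raise ValueError("only binary cross-entropy loss is supported")

    def to_config(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, config: dict) -> "TrainConfig":
        if "image_size" in config:
            config = {**config, "image_size": tuple(config["image_size"])}
        return cls(**config)


@dataclass
class RunRecord:
    """Outcome of one variant's train/evaluate cycle."""

    variant: str
    parameter_count: int
    train_metrics: MetricReport | None = None
    test_metrics: MetricReport | None = None
    loss_history: list[float] = field(default_factory=list)
    wall_time: float = 0.0  # informational only; never compared
    seed: int = 0


def easy_suite_config(seed: int = 0) -> TrainConfig:
    """Desk-scale protocol: 64x64, 5 epochs, Adam 1e-3, batch 10."""
    return TrainConfig(image_size=(64, 64), epochs=5, batch_size=10,
                       learning_rate=1e-3, seed=seed)


def easy_suite_params(seed: int = 0) -> PhantomParams:
    """Noise-free, rib-free, high-contrast phantoms at 64x64."""
    return PhantomParams(size=(64, 64), noise_sigma=0.0, rib_amplitude=0.0,
                         background_level=0.85, lung_contrast=0.55, seed=seed)


def split_dataset(manifest: pd.DataFrame, fraction: float = 0.8, seed: int = 0,
                  stratify: bool = True) -> tuple[list[str], list[str]]:
    """Seeded, disjoint, exhaustive train/test partition of manifest ids.

    Unstratified: train takes ``floor(fraction * n)`` of a seeded shuffle.
    Stratified: the floor rule is applied inside each class, so the class
    composition of the two sides matches the dataset.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = manifest["identifier"].astype(str).to_numpy()
    if not stratify:
        order = rng.permutation(len(ids))
        n_train = math.floor(fraction * len(ids))
        return list(ids[order[:n_train]]), list(ids[order[n_train:]])
    train: list[str] = []
    test: list[str] = []
    labels = manifest["class_label"].astype(str).to_numpy()
    for cls in sorted(set(labels)):
        cls_ids = ids[labels == cls]
        if len(cls_ids) < 2:
            raise ValueError(f"stratum {cls!r} has fewer than 2 items")
        order = rng.permutation(len(cls_ids))
        n_train = math.floor(fraction * len(cls_ids))
        train += list(cls_ids[order[:n_train]])
        test += list(cls_ids[order[n_train:]])
    return train, test


def _to_arrays(pairs: list[SegmentationPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in pairs])[:, None].astype(np.float32)
    y = np.stack([p.mask for p in pairs])[:, None].astype(np.float32)
    return x, y


def train_model(model: UNet, train_pairs: list[SegmentationPair],
                config: TrainConfig) -> RunRecord:
    """Minimize pixelwise BCE with Adam; fully seeded, per-epoch mean loss.

    Returns a partial :class:`RunRecord` (loss history, wall time); metric
    reports are attached by the caller after evaluation.
    """
    if not train_pairs:
        raise ValueError("no training pairs")
    x, y = _to_arrays(train_pairs)
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(x[idx])
            loss, dlogits = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; "
                    "try a lower learning rate")
            model.zero_grad()
            model.backward(dlogits)
            opt.step(model.named_parameters(), model.named_grads())
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.info("%s epoch %d/%d loss %.5f", model.spec.name, epoch + 1,
                    config.epochs, history[-1])
    return RunRecord(variant=model.spec.name, parameter_count=model.parameter_count,
                     loss_history=history, wall_time=time.perf_counter() - t0,
                     seed=config.seed)


def evaluate_model(model: UNet, pairs: list[SegmentationPair],
                   threshold: float = 0.5, batch_size: int = 20) -> MetricReport:
    """Threshold model probabilities and score them against the true masks."""
    x, _ = _to_arrays(pairs)
    triples = []
    for start in range(0, len(pairs), batch_size):
        batch = pairs[start : start + batch_size]
        pred = model.predict_mask(x[start : start + len(batch)], threshold)
        for p, pair in zip(pred, batch):
            triples.append((p[0], pair.mask, pair.identifier))
    return evaluate_dataset(triples)


def _to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for row in df.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _write_panels(model: UNet, pairs: list[SegmentationPair], path: Path,
                  threshold: float, k: int = 4) -> None:
    """Side-by-side image / true mask / predicted mask panels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample = pairs[:k]
    x, _ = _to_arrays(sample)
    pred = model.predict_mask(x, threshold)
    fig, axes = plt.subplots(len(sample), 3, figsize=(7, 2.3 * len(sample)),
                             squeeze=False)
    for i, pair in enumerate(sample):
        for j, (arr, title) in enumerate([(pair.image, "image"),
                                          (pair.mask, "actual mask"),
                                          (pred[i, 0], "predicted mask")]):
            axes[i][j].imshow(arr, cmap="gray", vmin=0, vmax=1)
            axes[i][j].set_axis_off()
            if i == 0:
                axes[i][j].set_title(title)
    fig.suptitle(model.spec.name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_benchmark(variants: list[str | VariantSpec], data_dir: str | Path,
                  config: TrainConfig, out_dir: str | Path,
                  panels: int = 4) -> list[RunRecord]:
    """Run the full workflow for each variant and write comparison reports.

    Per variant: build (with the parameter audit), train on the 80% split,
    evaluate both splits with IoU and Dice, and emit a parameter table, a
    metrics table (CSV + Markdown) and actual-vs-predicted panels. A failing
    variant is logged and skipped; the remaining records are still written.
    """
    if not variants:
        raise ValueError("no variants requested")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = scan_dataset(data_dir)
    pairs = load_pairs(manifest, data_dir)
    pairs = [preprocess_pair(p, config.image_size, config.gaussian_kernel,
                             config.gaussian_sigma) for p in pairs]
    by_id = {p.identifier: p for p in pairs}
    train_ids, test_ids = split_dataset(manifest, config.split_fraction,
                                        config.seed, config.stratify)
    if set(train_ids) & set(test_ids):
        raise RuntimeError("train/test leakage: split produced overlapping ids")
    train_pairs = [by_id[i] for i in train_ids]
    test_pairs = [by_id[i] for i in test_ids]
    pd.DataFrame({"identifier": train_ids + test_ids,
                  "split": ["train"] * len(train_ids) + ["test"] * len(test_ids)}
                 ).to_csv(out_dir / "split.csv", index=False)

    records: list[RunRecord] = []
    failures = 0
    for variant in variants:
        spec = resolve_variant(variant) if isinstance(variant, str) else variant
        try:
            model = build_unet(spec, seed=config.seed)
            audit = closed_form_param_count(spec)
            record = train_model(model, train_pairs, config)
            if record.parameter_count != audit:
                raise AssertionError(
                    f"parameter audit mismatch for {spec.name}: "
                    f"{record.parameter_count} vs closed form {audit}")
            record.train_metrics = evaluate_model(model, train_pairs,
                                                  config.threshold, config.batch_size)
            record.test_metrics = evaluate_model(model, test_pairs,
                                                 config.threshold, config.batch_size)
            if panels > 0:
                panel_dir = out_dir / "panels"
                panel_dir.mkdir(exist_ok=True)
                _write_panels(model, test_pairs, panel_dir / f"{spec.name}.png",
                              config.threshold, panels)
            model.save_weights(out_dir / f"{spec.name}.weights.npz")
            records.append(record)
        except Exception:
            failures += 1
            logger.exception("variant %s failed; skipping", spec.name)

    h, w = config.image_size
    params_df = pd.DataFrame([
        {"model": r.variant, "image_size": f"{h} x {w}",
         "total_params": r.parameter_count,
         "wall_time_s (informational)": round(r.wall_time, 2)}
        for r in records])
    metrics_rows = []
    for r in records:
        for process, rep in (("train", r.train_metrics), ("test", r.test_metrics)):
            metrics_rows.append({
                "model": r.variant, "process": process,
                "dice_micro": round(rep.micro_dice, 4),
                "iou_micro": round(rep.micro_iou, 4),
                "dice_macro": round(rep.macro_dice, 4),
                "iou_macro": round(rep.macro_iou, 4),
            })
    metrics_df = pd.DataFrame(metrics_rows)
    params_df.to_csv(out_dir / "params_table.csv", index=False)
    metrics_df.to_csv(out_dir / "metrics_table.csv", index=False)
    (out_dir / "params_table.md").write_text(_to_markdown(params_df))
    (out_dir / "metrics_table.md").write_text(_to_markdown(metrics_df))

    if failures and not records:
        raise RuntimeError("all variants failed")
    if failures:
        logger.warning("%d variant(s) failed; reports cover the rest", failures)
    return records
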