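# unetbench

A configurable, auditable benchmark of eight U-Net variants for lung-field
segmentation in chest radiographs — four **depth** variants (U-Net7/9/11/13:
3–6 encoder stages with a doubling filter schedule starting at 64/32/16/8)
and four **width** variants (U-Net16/32/64/128: the 9-layer layout with a
fixed filter count everywhere). It is aimed at people studying how depth and
width trade off against segmentation accuracy and model size in medical
imaging, and at anyone who wants a fully seeded, dependency-light
segmentation pipeline they can verify end to end.

The package provides:

- **Architecture construction with an exact audit.** Every variant is built
  from a declarative spec; the built network's scalar parameter count must
  equal an independent closed-form sum `Σ (c_in·c_out·k² + c_out)` over the
  stage layout. The five reference audits are, exactly:
  U-Net7 7,696,193 · U-Net16 52,993 · U-Net32 210,945 · U-Net64 841,729 ·
  U-Net128 3,362,817.
- **The preprocessing chain**: resize (bilinear image / nearest mask),
  3×3 σ=0.5 Gaussian denoise, histogram equalization + min-max scaling.
- **Overlap metrics**: pixelwise confusion counts, IoU = TP/(TP+FN+FP) and
  Dice = 2TP/((TP+FN)+(TP+FP)), per-image plus micro/macro aggregates —
  with the identity Dice = 2·IoU/(1+IoU) enforced in tests (so Dice ≥ IoU
  in every honest table).
- **A seeded phantom generator**: chest-radiograph-like images (two
  elliptical lung fields, rib stripes, noise) with exact ground-truth
  masks, so the whole pipeline is testable without downloading anything.
- **A train/evaluate harness**: seeded 80/20 stratified split, Adam + binary
  cross-entropy training (numpy, manual backprop — no deep-learning
  framework required), and comparison reports (parameter table, metrics
  table, actual-vs-predicted panels).

See `docs/methods.md` for the model conventions, numerical choices and
limitations.

## Worked example

Generate 200 easy phantoms, train the two cheapest width variants, and
report both metrics on the held-out 20 %:

```python
from unetbench import (easy_suite_config, easy_suite_params,
                       generate_dataset, run_benchmark)

generate_dataset(200, easy_suite_params(seed=0), "easy_ds")
records = run_benchmark(["U-Net16", "U-Net32"], "easy_ds",
                        easy_suite_config(seed=0), "results_easy")
for r in records:
    print(f"{r.variant}: params={r.parameter_count:,} "
          f"test micro Dice {r.test_metrics.micro_dice:.4f} "
          f"IoU {r.test_metrics.micro_iou:.4f}")
```

prints (deterministically, for seed 0):

```
U-Net16: params=52,993 test micro Dice 0.9982 IoU 0.9964
U-Net32: params=210,945 test micro Dice 0.9999 IoU 0.9998
```

Dice and IoU here are pooled-pixel ("micro") scores on the 40 held-out
phantoms: both variants recover essentially every lung pixel on this
noise-free task, and Dice ≥ IoU as the algebra requires. `results_easy/`
also contains `params_table.csv` (with informational wall-times),
`metrics_table.csv`, per-variant weight checkpoints and side-by-side
image / actual mask / predicted mask panels.

The same things are available from a shell:

```sh
unetbench build --variant U-Net9 --audit     # layer table + parameter count
unetbench synth --out ds --n 30 --size 64    # phantom dataset
unetbench run --variants U-Net16,U-Net32 --data ds --out results
unetbench evaluate --pred results/pred --truth ds/masks --report report.csv
```

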