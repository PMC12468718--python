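# arunet

Residual-attention U-Net toolkit for brain-tumor MRI segmentation.

Accurate delineation of tumors in axial brain MRI slices is complicated by
low-frequency coil bias fields, acquisition noise, and strong class imbalance
between tumor types.  This package implements a complete, CPU-only workflow
for that problem, aimed at researchers who want a fully inspectable,
deterministic reference implementation rather than a GPU training harness:

* **Preprocessing** — contrast-limited adaptive histogram equalisation
  (CLAHE), non-local means denoising, and edge-preserving (linear) Kuwahara
  filtering, applied in that fixed order.
* **Attention primitives** — adaptive channel attention (ACA: a 1D
  convolution over the globally pooled channel vector with kernel size
  `k = odd(⌊|log₂C/γ + β/γ|⌋)`, γ=2, β=1) and dimensional-space triplet
  attention (DTA: three branches pooling one tensor axis each, gated by
  `ω = tanh(α·ψ(·))` and averaged `y = ⅓(x̂₁ω₁ + x̂₂ω₂ + x̂₃ω₃)`).
* **Networks** — four nested U-shaped variants: `unet`, `unet_res`
  (residual blocks), `unet_res_aca` (+ encoder channel attention), and
  `arunet` (+ a context-information-transmission stem with
  `R₁ = Q₁ + Q₃` and decoder triplet attention).
* **Training** — class-weighted categorical cross-entropy
  `L = −(1/N)ΣΣ y_ic log ŷ_ic`, class-balanced mini-batches, stratified
  6:2:2 splits, Adam, early stopping on validation loss, checkpoint
  selection on validation weighted F1.
* **Metrics** — per-class and aggregated accuracy, precision, recall, F1,
  IoU = TP/(TP+FP+FN) and DSC = 2TP/(2TP+FP+FN).
* **Synthetic phantoms** — a seeded generator of brain-like images with
  class-styled tumor blobs, multiplicative bias fields and noise, so the
  whole pipeline runs and tests without any dataset download.

The networks run on a small numpy reverse-mode autograd engine bundled in
`arunet.nn`; everything is float64, single-CPU, and bit-deterministic under
a fixed seed.

## Worked example

```python
import numpy as np
from arunet.synthetic import PhantomSpec, generate_examples
from arunet.training import LabeledExample, TrainConfig, train
from arunet.network import build_model
from arunet.metrics import confusion_counts, foreground_mask, metric_suite

spec = PhantomSpec(image_size=64)
tr = [LabeledExample(e.image, e.mask, e.class_label)
      for e in generate_examples(spec, per_class=10, seed=7)]
va = [LabeledExample(e.image, e.mask, e.class_label)
      for e in generate_examples(spec, per_class=2, seed=9007)]

model = build_model("arunet", depth=3, base_width=8, n_classes=6, seed=7)
cfg = TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=200,
                  patience=200, seed=7, max_steps=200)
result = train(model, tr, va, cfg)
model.load_state_dict(result.best_state)

images = np.stack([e.image for e in va]) / 255.0
fg = foreground_mask(model.predict_proba(images))
true = np.stack([e.mask for e in va]) > 0
report = metric_suite(confusion_counts(fg.astype(int), true.astype(int), 2))
print(f"foreground DSC: {report.dsc[1]:.3f}")
```

This trains the tiny (31,574-parameter) variant for 200 optimisation steps
on sixty 64×64 phantoms and prints

```
foreground DSC: 0.897
```

the Dice overlap between the predicted tumor region (tumor probability
`1 − p_background > 0.5`) and the ground-truth blobs on twelve held-out
phantoms — i.e. the tiny network localises the lesions almost completely
after a two-minute CPU run.

The same workflow is available from the shell:

```sh
arunet synth --out data/raw --per-class 10 --size 128 --seed 7
arunet preprocess --in data/raw --out data/pre
arunet run --out runs/tiny --seed 7 --tiny
```

## Layout

```
src/arunet/
  preprocess.py   CLAHE, non-local means, Kuwahara, pipeline
  attention.py    functional attention primitives (numpy, channels-last)
  nn/             autograd engine, layers, attention modules, Adam
  network.py      blocks, the four variants, checkpoints
  training.py     splits, weighting, balanced batches, training loop
  metrics.py      confusion counts, six-metric suite, weighted F1
  synthetic.py    seeded phantom generator and dataset writer
  io.py, cli.py   dataset/config I/O and the `arunet` command
docs/methods.md   model and design notes
tests/            pytest suite (unit, property, acceptance)
```
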