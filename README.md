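# cuffseg

Supraspinatus segmentation from shoulder MRI: an attention-gated
LinkNet-style encoder-decoder with a DenseASPP bridge, plus the full
experimental scaffolding — synthetic phantom benchmark, subject-level data
handling, training recipe, pixel-count metrics, and a five-variant
ablation harness.

## Who this is for

Researchers in musculoskeletal image analysis who want a self-contained,
reproducible implementation of a crescent-shaped-muscle segmentation
pipeline.  Rotator cuff tears most often involve the supraspinatus, and
segmenting it on oblique-coronal MRI is complicated by adjacent muscles
with near-identical grayscale values.  Clinical MRI datasets for this task
are private, so the package ships a phantom generator that reproduces the
structural difficulties (elongated crescent target, close-intensity
distractors, correlated slices per subject) and makes every pipeline stage
testable end to end.

## The model

The segmentation network `f_theta : [0,1]^{3 x S x S} -> (0,1)^{S x S}`
(S divisible by 32) is a LinkNet-style encoder-decoder:

* **Encoder** — ResNet-18/34: stride-2 stem + max-pool, four residual
  stages of widths 64/128/256/512; total stride 32, so a 512-pixel input
  yields a 16 x 16 x 512 bottleneck.
* **Channel attention** (optional) — squeeze-excitation gates
  `g = sigma(W2 relu(W1 GAP(f)))` applied to each skip feature at the
  junction before the additive fusion; reduction ratio r = 16.
* **DenseASPP bridge** (optional) — densely connected dilated branches at
  rates (3, 6, 12, 18, 24); branch i consumes `concat(f4, y_1..y_{i-1})`,
  and a 1x1 projection plus residual addition restores 512 channels.
* **Decoder** — four LinkNet blocks (1x1 reduce, 3x3 transposed conv
  stride 2, 1x1 expand) with additive skip fusion, then a transposed-conv
  head and logistic output.

Training: BCE on probabilities, Adam, batch 2, lr 1e-4, 30 epochs.
Evaluation pools TP/FP/FN/TN pixel counts over the whole test set, then

    Precision = TP/(TP+FP) x 100 %
    IoU       = TP/(TP+FP+FN) x 100 %
    Dice      = 2 TP/((TP+FP)+(TP+FN)) x 100 %

Under pooled counts, Dice = 2 IoU/(1+IoU) — an identity the bundled table
audit verifies on ten published benchmark rows.

The ablation grid maps names onto architecture flags: `baseline`
(depth 18), `scheme1` (depth 34), `scheme2` (+attention), `scheme3`
(+DenseASPP), `full` (both).

Everything runs on a compact NumPy autograd engine (`cuffseg.nn`) with
im2col convolutions and finite-difference-verified gradients; no GPU or
deep-learning framework is required.

## Worked example

Train the full variant on small, separable phantoms and evaluate on
held-out subjects:

```python
from cuffseg import PhantomConfig, TrainConfig, build_model, generate_dataset, train
from cuffseg.dataio import Manifest, SplitSpec, split_by_subject
from cuffseg.metrics import evaluate

cfg = PhantomConfig(image_size=64, contrast=255, noise_sigma=0,
                    slices_per_subject=(3, 3), seed=0)
ds = generate_dataset(cfg, 6)                      # 6 subjects, 18 slices
tr, va, te = split_by_subject(Manifest(ds.manifest), SplitSpec(seed=0))
key = {(s.subject_id, s.slice_index): s for s in ds.samples}
pick = lambda m: [key[(r.subject_id, r.slice_index)]
                  for r in m.rows.itertuples(index=False)]

model = build_model("full", seed=0)
history, _ = train(model, pick(tr), pick(va), TrainConfig(epochs=25, seed=0))
rep = evaluate(model, pick(te), 0.5)
print(f"test: precision {rep.precision:.2f}  iou {rep.iou:.2f}  dice {rep.dice:.2f}")
```

which prints (loss falling as the net separates target from background,
then the pooled held-out metrics):

```
epoch  1  loss 0.6104  val dice 6.70
epoch  5  loss 0.4583  val dice 30.42
epoch 10  loss 0.3559  val dice 57.08
epoch 15  loss 0.2814  val dice 66.54
epoch 20  loss 0.2291  val dice 72.14
epoch 25  loss 0.1919  val dice 77.27
test: precision 82.55  iou 68.16  dice 81.06
```

Interpretation: with only 12 training slices at 64 pixels the model
reaches a pooled held-out Dice of 81 % on noiseless phantoms; more
subjects, higher resolution, or longer training push it higher (the
learning-sanity check in the test suite reaches a training Dice of 95 %
on 40 phantoms at 128 pixels within 15 epochs).  The same flow is
available from the shell:

```bash
cuffseg generate --out-dir data --n-subjects 10 --seed 0
cuffseg split --manifest data/manifest.csv --out-dir splits --seed 0
cuffseg augment --manifest splits/train.csv --out-dir augmented
cuffseg train --train-manifest augmented/manifest.csv \
              --val-manifest splits/val.csv --out-dir run
cuffseg evaluate --checkpoint run/best.npz --manifest splits/test.csv --out report.json
cuffseg ablate --config config.yaml --out-dir ablation   # five-variant table
```

Auditing the published benchmark rows for pooled-count consistency:

```
$ cuffseg audit-tables
     table    model   pre   iou  dice  dice_expected  consistent
comparison      FCN 98.28 65.07 78.84          78.84        True
...
10/10 rows consistent
```

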