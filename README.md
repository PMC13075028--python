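# tideseg

Boundary-aware semantic segmentation of floating green-tide algae
(*Ulva prolifera*) in multispectral remote-sensing imagery.

Green-tide blooms drift as a mixture of large irregular filaments and small
scattered fragments whose contours blur into the surrounding water. Plain
encoder–decoder segmentation networks optimise for regional class consistency
and tend to smooth over exactly those low-contrast boundaries, so area
estimates and contour maps suffer. `tideseg` implements a segmentation
network and training pipeline built around two boundary-oriented ideas, for
researchers and practitioners who map algal blooms from coastal-zone imagery:

1. **Efficient channel attention (ECA) on shallow features.** The encoder is
   a four-stage hierarchical (SegFormer-style) transformer producing a
   pyramid C1..C4 at strides 4/8/16/32. The shallow stages C1, C2 carry the
   edge and texture information. For a feature map F ∈ ℝ^{H×W×C}, ECA
   computes a channel descriptor by global average pooling,

       z_c = (1 / HW) Σ_i Σ_j F_{i,j,c},

   passes it through a bias-free 1-D convolution over the channel axis with
   adaptive odd kernel size k = odd(log₂(C)/γ + b) (γ=2, b=1; C=64 and
   C=128 both give k=5), gates it with a sigmoid s = σ(Conv1D_k(z)) ∈ (0,1)^C
   and rescales the map channel-wise, F̂_{i,j,c} = F_{i,j,c}·s_c. The whole
   module costs 10 trainable parameters in the base configuration.

2. **A parallel boundary supervision branch.** The recalibrated shallow
   features C1′ and C2′ (the same tensors the decoder receives) are fused —
   C2′ upsampled ×2 and concatenated, giving 128×128×192 for a 512-px input —
   then passed through a 3×3 conv + BN + ReLU (64 channels) and a 1×1 conv
   into a single-channel boundary logits map, bilinearly upsampled to input
   resolution. It is supervised with `BCEWithLogits` against contour labels
   generated from the ground-truth mask by a morphological gradient
   (dilation − erosion, 3×3 square structuring element). The joint objective
   is

       L_total = L_seg + λ · L_bnd,     λ = 0.5 by default,

   with L_seg the pixel-wise two-class cross-entropy. Both loss terms
   backpropagate into the shallow features and the ECA kernels.

Evaluation includes region metrics (mIoU, F1, precision, recall) and
boundary metrics: the boundary F1-score (BF-score) with a δ = 3 px inclusive
Euclidean matching tolerance, and the symmetric Hausdorff distance between
contour pixel sets.

The package also provides the full preprocessing pipeline ((NIR, G, B)
compositing, 2–98 percentile stretch, 512×512 tiling, train-only
augmentation), a deterministic synthetic-scene generator that emulates the
statistics of coastal-zone green-tide imagery so everything is testable
without restricted satellite data, a training/evaluation harness with λ and
ECA-placement ablation runners, and a `tideseg` command-line interface.

The compute core is a small pure-NumPy reverse-mode autodiff engine
(`tideseg.nn`) — convolutions, efficient self-attention, Mix-FFN, batch/layer
norm, bilinear resampling, AdamW — whose adjoints are verified against finite
differences in the test-suite.

## Worked example

Train the reduced-scale network on easy synthetic scenes and evaluate on a
held-out split (about two minutes on one CPU):

```python
from dataclasses import replace
from tideseg import harness, synth
from tideseg.model import ModelConfig, SegmentationModel

params = replace(synth.difficulty_presets()["easy"], side=128)
data = synth.generate_tile_splits(8, params, split=(0.5, 0.25, 0.25),
                                  master_seed=3, tile_size=64)
cfg = harness.TrainConfig(input_size=64, iters=200, batch_size=4, lr=1e-3,
                          warmup_iters=20, lambda_bnd=0.5, seed=0, val_every=1000)
model = SegmentationModel(ModelConfig.from_variant("micro"), seed=0)
result = harness.train(model, data, cfg)
report, _ = harness.evaluate(model, data["test"])
print(f"final training loss {result.loss_log.l_total.iloc[-1]:.3f}")
print(f"mIoU {report.miou:.3f}  F1 {report.f1:.3f}  "
      f"BF-score {report.bf_score:.3f}  HD {report.hd:.2f} px")
```

Output:

```
final training loss 0.207
mIoU 0.833  F1 0.833  BF-score 0.991  HD 5.46 px
```

The joint loss falls from ~1.1 at initialisation to ~0.2; on the held-out
tiles the model overlaps 83% of algae/background area on average (mIoU),
places almost every predicted contour pixel within 3 px of a true contour
(BF-score 0.991), and its worst contour deviation averages 5.5 px (HD).

From the shell the same workflow is:

```bash
tideseg synth --preset default --n-scenes 20 --seed 7 --out data/
tideseg train --config config.yaml --data data/ --out runs/exp1
tideseg eval --checkpoint runs/exp1/checkpoint.npz --data data/ --split test --out metrics.csv
tideseg params --variant b2
```

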