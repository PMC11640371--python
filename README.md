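# cadeye

Multi-disease classification of retinal fundus photographs: a complete,
desk-scale pipeline for telling apart **normal** retinas and four disorders —
**diabetic retinopathy** (dot hemorrhages, exudates), **hypertensive
retinopathy** (arteriolar narrowing, cotton-wool spots), **glaucoma**
(enlarged optic cup) and **contrast/cataract-type** opacity (global haze) —
aimed at researchers who want a reproducible, fully-tested reference
implementation of this class of CAD system rather than a clinical product.

## The method

1. **Fluorescence-simulation preprocessing.** Each RGB image is split into
   channels, the green channel is amplified, `G' = min(round(α·G), 255)` with
   α = 2.0 by default, the image is re-merged as `(R, G', B)` and the blue
   channel is optionally zeroed, emphasizing vascular/lesion structure the
   way fluorescein angiography does visually. A HOT-colormap branch exists
   for visualization only. Images are then resized to 700 × 600 px.
2. **Balanced augmentation.** An AutoAugment-style policy (pairs of
   probabilistic ops: rotation ≤ 15°, translation ≤ 10 %, shear ≤ 8°,
   photometric jitter ± 20 %, cutout ≤ 10 % area, horizontal flips)
   oversamples minority classes until the training split is balanced; the
   test split is never touched.
3. **Frozen dual-backbone feature extraction.** Two small convolutional
   networks — one of inverted-residual (MobileNetV2-family) blocks, one of
   MBConv blocks with squeeze-and-excitation gates (EfficientNetB0-family) —
   are frozen and applied to every image; the final convolutional stage is
   collapsed by global average pooling, `x_pooled,c = mean_{i,j} X[i,j,c]`.
4. **Feature-fusion head.** The two pooled vectors are fused (concatenation
   by default; element-wise sum/product via a learned alignment transform)
   and classified by a dense softmax head trained with Adam on categorical
   cross-entropy. Two head variants: *basic* `Dense(128, ReLU) →
   Dense(K, softmax)` and *extended* — three width-preserving dense blocks
   (per-feature transform, ReLU, batch norm `y = γ·(x−μ_B)/√(σ²_B+ε) + β`,
   additive skip) followed by an 850-unit layer.
5. **Gradient-boosted-tree head.** Exact-greedy second-order boosting on the
   head's penultimate features: per round, `g_i = p_i − 1[y_i]`,
   `h_i = p_i(1−p_i)`, one regression tree per class with leaf weight
   `−G/(H+λ)`, accumulated with learning rate η over τ rounds.
6. **Grad-CAM + evaluation.** Saliency maps over either backbone's final
   feature map (channel weights = spatially averaged class-score gradients),
   and a 5-class evaluation report: confusion matrix, one-vs-rest
   sensitivity/specificity/F1 with macro averaging.

Everything runs end-to-end on a built-in synthetic fundus generator (seeded,
parametric renderings of retinal field, optic disc/cup, vessel trees and
class-specific lesions), so no clinical data are needed to exercise or test
any stage.

## Worked example

```python
from cadeye import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, workdir="runs/demo", n_per_class=50, epochs=15)
result = run_pipeline(cfg)
for head, rep in result.reports.items():
    print(f"{head:8s} accuracy={rep.accuracy:.3f} "
          f"macro SE={rep.macro_sensitivity:.3f} SP={rep.macro_specificity:.3f} "
          f"F1={rep.macro_f1:.3f}")
print(result.reports["gbt"].confusion)
```

prints (about two minutes on one CPU):

```
softmax  accuracy=0.925 macro SE=0.925 SP=0.981 F1=0.924
gbt      accuracy=0.850 macro SE=0.850 SP=0.963 F1=0.850
[[7 0 0 1 0]
 [0 7 0 1 0]
 [0 0 7 1 0]
 [1 1 1 5 0]
 [0 0 0 0 8]]
```

i.e. 250 synthetic images are generated, preprocessed and split 85/15; the
fused softmax head classifies 37 of the 40 held-out images correctly, and the
confusion matrix (rows = true class, in the order normal, diabetic
retinopathy, hypertensive retinopathy, glaucoma, contrast) shows the residual
confusions involve glaucoma, whose signature is the most localized. Larger
sets sharpen this: at 100 images per class both heads exceed 90 % held-out
accuracy. The run directory keeps the resolved config, per-epoch history,
model checkpoints, JSON reports and a reproducibility record; identical
config + seed reproduces identical reports.

The same pipeline is available from the shell:

```bash
cadeye simulate-data --n-per-class 50 --seed 1 --out data/
cadeye preprocess --alpha 2.0 --in data/ --out processed/
cadeye train --config config.yaml --head both
cadeye explain --run-dir runs/demo --image img.png --target glaucoma --out cam.png
cadeye compare --config a.yaml --config b.yaml
```

User-supplied image folders (one subdirectory per class, PNG/JPEG) are
accepted anywhere the synthetic generator is used, via `data_dir` in the
config.

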