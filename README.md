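# leaffuse

Diagnosing plant nutrient deficiencies from leaf photographs by **fusing
handcrafted shallow features with deep-network embeddings**. Deficiencies of
N, P, K, Mg and Fe change a leaf's color and texture in characteristic ways
(uniform yellowing, interveinal chlorosis, reticulate pallor, reddish veins,
yellow crinkled margins), and while deep convolutional embeddings capture
most of that signal, visually similar deficiencies — iron and nitrogen
chlorosis in particular — remain confusable. Concatenating an explicit
color/texture descriptor with the learned embedding restores the missing
separation.

The package is aimed at plant-phenotyping and agricultural image-analysis
work: it provides the full pipeline as a library plus a thin `leaffuse` CLI,
and ships seeded synthetic-data generators (leaf images and feature-space
clusters) so every stage is testable without a proprietary image collection.

## Method

For an RGB leaf image the pipeline computes:

1. **Segmentation** — iterative threshold selection (Ridler–Calvard): split
   the gray histogram at T into regions R₁, R₂ with means u₁, u₂ and iterate
   T ← (u₁+u₂)/2 to convergence; keep the largest connected component and
   fill holes.
2. **Shallow features (792-dim)** — over leaf pixels only:
   - HSI color histogram, 256 bins per channel (H, S, I), 768 values, with
     I = (R+G+B)/3, S = 1 − 3·min(R,G,B)/(R+G+B), and the arccos hue formula
     (H ∈ [0, 2π));
   - gray-level co-occurrence matrix (GLCM) statistics — ASM, contrast,
     correlation, entropy, inverse difference moment, homogeneity — at
     0°, 45°, 90°, 135°, 24 values.
3. **Depth features** — the output of the last normalization layer (the
   pooled pre-classifier embedding) of a convolutional backbone; the
   reference architecture is a ConvNeXt-style network with stages
   C = (128, 256, 512, 1024), B = (3, 3, 27, 3), depthwise 7×7 kernels and
   inverted bottlenecks (1024-dim embedding). A small 3-conv test backbone
   and a plugin protocol for arbitrary extractors are included.
4. **Serial fusion** — z-scored concatenation [shallow | depth]
   (792 + 1024 = 1816 for the reference backbone), statistics fitted on the
   training split only.
5. **Heads** — F-Net (dense), FC-Net (1-D conv recoding), FA-Net
   (multi-head attention recoding: the vector is reshaped into tokens and
   recoded by softmax(QKᵀ/√Dₖ)V per head before classification).
6. **Evaluation** — confusion matrix, per-class/macro precision, recall, F1,
   macro-averaged precision (AP), accuracy, one-vs-rest ROC/AUC, plus SVM
   (RBF) and random-forest reference baselines.

All neural components run on a small self-contained reverse-mode autodiff
engine (`leaffuse.autodiff`) in pure numpy — deterministic and dependency-light.

## Worked example

```python
import numpy as np
from leaffuse import (TrainConfig, compare_pipelines, default_cluster_spec,
                      generate_feature_clusters, stratified_split)

spec = default_cluster_spec()           # Fe/N depth distributions coincide
shallow, depth, y = generate_feature_clusters(spec, n_per_class=60, seed=5)
split = stratified_split(y, seed=6)     # 7:2:1 train/val/test

df = compare_pipelines(
    {"depth": depth, "fused": np.concatenate([shallow, depth], axis=1)},
    y, split, head_types=("FA",),
    config=TrainConfig(epochs=40, seed=7, lr_switch_epoch=20),
    head_kwargs={"d_model": 16, "hidden_dim": 64})
print(df.round(2).to_string(index=False))
```

prints

```
source head  accuracy  precision  recall    f1    ap
 depth   FA     80.56      81.94   80.56 80.70 81.94
 fused   FA     91.67      91.90   91.67 91.61 91.90
```

The depth-only head is capped near 5/6 ≈ 83% because one class pair is
statistically identical in the depth block; fusing in the shallow features
recovers the pair and lifts test accuracy by 11 points. The scripts in
`examples/` walk through segmentation/extraction, the attention layer, this
experiment, and the full image pipeline (`examples/04_full_pipeline.py`
reaches 100% test accuracy on 120 synthetic leaves in a few seconds).

## Command line

```sh
leaffuse generate --n-per-class 20 --size 128 --seed 1 --out data
leaffuse segment data/Fe/img_0000.png --out mask.png
leaffuse extract-shallow data --out shallow.csv
leaffuse extract-depth data --backbone tiny --out depth.csv
leaffuse fuse shallow.csv depth.csv --out fused.csv
leaffuse train --head fa --features fused.csv --out model.npz
leaffuse evaluate --model model.npz --features fused.csv --out report.json
leaffuse run --seed 5          # whole pipeline from a config
```

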