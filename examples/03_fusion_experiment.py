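"""Why fuse? A class pair indistinguishable in depth features is recovered.

Samples 6-class Gaussian clusters where the Fe and N classes share an
identical depth-block distribution (emulating two deficiencies that look
alike to a deep network) while their shallow-block means differ.  An
attention-recoding head is trained once on depth features alone and once on
the fused vector.
"""

import numpy as np

from leaffuse import (TrainConfig, compare_pipelines, default_cluster_spec,
                      generate_feature_clusters, stratified_split)

spec = default_cluster_spec()
shallow, depth, y = generate_feature_clusters(spec, n_per_class=60, seed=5)
split = stratified_split(y, seed=6)
print(f"{len(y)} samples, confusable pair (class indices): "
      f"{spec.confusable_pairs}")

df = compare_pipelines(
    {"depth": depth, "fused": np.concatenate([shallow, depth], axis=1)},
    y, split, head_types=("FA",),
    config=TrainConfig(epochs=40, seed=7, lr_switch_epoch=20),
    head_kwargs={"d_model": 16, "hidden_dim": 64})
print(df.round(2).to_string(index=False))
# Depth-only accuracy is capped near 5/6 ~ 83% because the planted pair is
# statistically identical in that block; fusing in the shallow features
# restores the missing separation and lifts test accuracy well above it.
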