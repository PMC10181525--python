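"""Segment a synthetic leaf and extract its 792-dim shallow descriptor.

Generates one magnesium-deficient leaf (interveinal yellow spots), separates
it from the dark background by iterative thresholding, and computes the HSI
color histogram plus GLCM texture statistics over the leaf pixels only.
"""

import numpy as np

from leaffuse import (default_recipes, extract_shallow, generate_leaf_image,
                      iterative_threshold, rgb_to_gray, segment_leaf)

img, truth = generate_leaf_image(default_recipes()["Mg"], size=128, seed=1)

state = iterative_threshold(rgb_to_gray(img))
print(f"threshold converged to T={state.T:.1f} "
      f"(region means {state.u1:.1f} / {state.u2:.1f}, "
      f"{state.iterations} iterations)")

mask = segment_leaf(img)
jac = (mask & truth).sum() / (mask | truth).sum()
print(f"mask overlap with ground truth: Jaccard {jac:.3f}")

vec = extract_shallow(img, mask)
print(f"shallow feature vector: {vec.shape[0]} values "
      f"(768 color histogram + 24 texture)")
print(f"first texture block (ASM, contrast, correlation, entropy, IDM, "
      f"homogeneity at 0 deg):\n{np.round(vec[768:774], 4)}")
# The threshold sits between the dark background (~30) and the leaf tissue;
# a Jaccard near 1 means the mask recovers the true leaf almost exactly, and
# the texture statistics summarize tissue granularity per direction.
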