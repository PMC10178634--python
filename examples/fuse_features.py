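"""Serial mid-value fusion of original-image and enhanced-image features.

Extracts toy-backbone features from synthetic images and their enhanced
versions, concatenates the two matrices column-wise, and keeps the columns
whose mean activation reaches the mid-value (min+max)/2 of the column
scores. The printed threshold and retained count show how the cutoff
roughly halves the score range, not the column count.
"""

from mammocad import (
    ImageFixtureSpec,
    enhance,
    extract_features,
    make_images,
    threshold_fuse,
    toy_backbone,
)

items = make_images(ImageFixtureSpec(n_per_class=6, seed=1))
labels = [it.label for it in items]
backbone = toy_backbone(seed=1, d=32)

f_orig = extract_features([it.image for it in items], labels, backbone, source_id="original")
f_enh = extract_features([enhance(it.image) for it in items], labels, backbone, source_id="enhanced")

fused = threshold_fuse(f_orig, f_enh, statistic="mean")
print(f"concatenated: {f_orig.n_features} + {f_enh.n_features} "
      f"= {f_orig.n_features + f_enh.n_features} columns")
print(f"column-score range: [{fused.scores.min():.4f}, {fused.scores.max():.4f}]")
print(f"mid-value threshold Fnc = {fused.threshold:.4f}")
print(f"retained {fused.retained_indices.size} columns -> fused matrix "
      f"{fused.matrix.n_samples}x{fused.matrix.n_features}")
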