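"""Contrast-enhance a synthetic low-contrast lesion image.

Generates one benign-style image (a bright plateau blob on a noisy dark
background), runs the two-stage enhancement (histogram remap + local
contrast stretch), and prints intensity statistics. The enhanced image
should have a larger intensity standard deviation — deviations from the
local mean are amplified, so the lesion stands out more.
"""

import numpy as np

from mammocad import EnhancementParams, ImageFixtureSpec, enhance, make_images

spec = ImageFixtureSpec(n_per_class=1, seed=0, contrast=40.0, noise_sigma=3.0)
benign = next(it for it in make_images(spec) if it.label == "benign")

params = EnhancementParams(K=0.8, beta=1.0, c=1.0, a=1.0, window=7)
out = enhance(benign.image, params)

print(f"input : mean {benign.image.mean():6.2f}  std {benign.image.std():6.2f}  "
      f"range [{benign.image.min():.1f}, {benign.image.max():.1f}]")
print(f"output: mean {out.mean():6.2f}  std {out.std():6.2f}  "
      f"range [{out.min():.1f}, {out.max():.1f}]")
print("std ratio (output/input):", round(out.std() / benign.image.std(), 3))
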