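"""Apply one randomly drawn instance of each transformation family to a frame.

For every family the script draws parameters from a representative range,
applies the transform, and prints how the frame changed: the polyp-mask area
(moved by image-based transforms, untouched by the others) and the mean
intensity (shifted by pixel-based transforms).  Masks always stay binary and
aligned with the image — that joint consistency is what makes these
augmentations safe for segmentation training.
"""

import numpy as np

from polypaug.synthetic import SyntheticConfig, generate_sample
from polypaug.transforms import apply_random_transform, spec_for

sample = generate_sample(SyntheticConfig(height=128, width=128, seed=3))
rng = np.random.default_rng(0)

families = [
    ("width_shift", 0.9), ("rotation", 90), ("shear", 45),
    ("zoom_in", (0.5, 1.0)), ("flip_vertical", True), ("elastic", (3000, 40)),
    ("brightness_independent", 125), ("contrast_independent", (0.4, 1.6)),
    ("specular", True), ("blur", 9),
]

print(f"{'family':<26}{'range':<14}{'mask px':>9}{'mean I':>9}")
print(f"{'(input)':<26}{'':<14}{sample.mask.sum():>9}{sample.image.mean():>9.1f}")
for name, value in families:
    out = apply_random_transform(sample, spec_for(name, value), rng)
    print(f"{name:<26}{str(value):<14}{out.mask.sum():>9}{out.image.mean():>9.1f}")
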