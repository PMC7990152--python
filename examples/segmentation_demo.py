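"""Threshold level-set segmentation on a noisy sphere.

Shows the two faces of the segmenter: with curvature weight 0 on
noiseless data it reduces exactly to double-thresholding (the window is
300-600 normalized units), while the default curvature weight 0.6
regularizes a noisy surface at almost no cost in volume accuracy.
"""

import numpy as np

from graftquant.levelset import LevelSetParams, segment, to_mask
from graftquant.volio import VolumeImage

shape = (48, 48, 48)
radius = 13
idx = np.indices(shape)
r = np.sqrt(((idx - (shape[0] - 1) / 2.0) ** 2).sum(axis=0))
clean = np.where(r < radius, 450.0, -200.0)
rng = np.random.default_rng(0)
noisy = clean + rng.normal(0, 60, shape)

analytic = 4 / 3 * np.pi * radius ** 3

vol = VolumeImage(clean, (0.16,) * 3, (0, 0, 0), "normalized")
fld, _ = segment(vol, LevelSetParams(curvature_weight=0.0))
mask = to_mask(fld).values
same = np.array_equal(mask, (clean >= 300) & (clean <= 600))
print(f"noiseless, curvature 0: identical to double-thresholding? {same}")

for cw in (0.0, 0.6):
    voln = VolumeImage(noisy, (0.16,) * 3, (0, 0, 0), "normalized")
    fld, rep = segment(voln, LevelSetParams(curvature_weight=cw))
    m = to_mask(fld).values
    faces = sum(np.abs(np.diff(m.astype(int), axis=ax)).sum() for ax in range(3))
    print(
        f"noisy, curvature {cw}: volume error "
        f"{100 * (m.sum() / analytic - 1):+.2f}%, surface faces {faces}, "
        f"{rep.iterations} iterations"
    )
print("Higher curvature weight -> smoother surface (fewer boundary faces)")
print("at essentially unchanged volume: that is what the weight is for.")
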