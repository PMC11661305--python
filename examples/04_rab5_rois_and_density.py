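"""Segment Rab5 puncta, pick ROIs with matched controls, compare densities.

Renders a puncta image (endocytic hot spots), segments it with rolling-ball +
Moments thresholding + particle filters, selects Rab5-positive ROIs
(< 0.3 um^2), samples congruent Rab5-negative control regions, and measures
the localization density in each set for a uniform localization field.
"""

import numpy as np

from smnd import simulate_puncta_image
from smnd.puncta import build_roi_set, segment_puncta

image, _ = simulate_puncta_image(12, area_um2=0.2, peak_intensity=200.0,
                                 background=20.0, shape=(384, 384), seed=3)
puncta = segment_puncta(image, pixel_size_um=0.1)
print(f"puncta segmented: {len(puncta)}  "
      f"(mean area {np.mean([p.area_um2 for p in puncta]):.2f} um^2)")

rng = np.random.default_rng(0)
locs = np.column_stack([rng.uniform(0, 38400, 40000), rng.uniform(0, 38400, 40000)])
mask = np.ones(image.shape, bool)
roi_set, table = build_roi_set(puncta, mask, locs, seed=0)

pos = table[table.type == "+"]
neg = table[table.type == "-"]
print(f"Rab5+ ROIs: {len(pos)}, matched Rab5- controls: {len(neg)}")
print(f"total areas: + {pos.area_um2.sum():.2f} um^2, - {neg.area_um2.sum():.2f} um^2")
print(f"mean density: + {pos.density_per_um2.mean():.1f} /um^2, "
      f"- {neg.density_per_um2.mean():.1f} /um^2")
# On a uniform field both densities estimate the same number (~27 /um^2 here);
# on real data a higher density in Rab5+ areas marks enrichment at endocytic
# hot spots.
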