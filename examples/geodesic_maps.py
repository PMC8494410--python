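"""Adaptive geodesic distance maps from a scribble.

Computes the AGD map on a two-region 2D image from a single seed stroke
and contrasts it with a pure spatial distance (intensity weight 0). The
intensity term makes the far region expensive to reach: its AGD values
jump at the boundary, which is what turns these maps into soft region
masks for the classifier.
"""

import numpy as np

from imlseg import AGDParams, ImageGeometry, normalize01
from imlseg.agd import agd_map
from imlseg.preprocess import standardize

geom = ImageGeometry(size=(32, 32), spacing=(1.0, 1.0), origin=(0.0, 0.0))
image = np.zeros((32, 32))
image[:, 16:] = 1.0  # right half is a different "tissue"
image = standardize(image)

seeds = np.zeros((32, 32), dtype=bool)
seeds[8:24, 4] = True  # a vertical stroke in the left region

spatial = normalize01(agd_map(image, geom, seeds,
                              AGDParams(intensity_weight=0.0, max_passes=64)))
adaptive = normalize01(agd_map(image, geom, seeds,
                               AGDParams(max_passes=64)))

left, right = (slice(None), slice(0, 16)), (slice(None), slice(16, None))
print("mean normalized distance, spatial only: "
      f"left {spatial[left].mean():.3f}  right {spatial[right].mean():.3f}")
print("mean normalized distance, adaptive:     "
      f"left {adaptive[left].mean():.3f}  right {adaptive[right].mean():.3f}")
print("The adaptive map separates the regions far more sharply than "
      "spatial distance alone — the intensity jump dominates the path cost.")
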