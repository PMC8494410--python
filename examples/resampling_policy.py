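"""The isotropic resampling policy on realistic scan geometries.

Shows when resampling triggers (anisotropy beyond 0.1 mm, or 10 million
voxels or more) and which isotropic spacing the policy picks: the smallest
value, at least the finest original spacing, that brings the working grid
under 10 million voxels.
"""

import numpy as np

from imlseg import (
    ImageGeometry,
    PreprocessConfig,
    needs_resampling,
    target_isotropic_spacing,
)
from imlseg.preprocess import resampled_size

cfg = PreprocessConfig()
cases = [
    ("isotropic head MRI", (155, 240, 240), (1.0, 1.0, 1.0)),
    ("thick-slice body CT", (200, 512, 512), (3.0, 0.5, 0.5)),
    ("large 2D mammogram", (4000, 4000), (1.0, 1.0)),
]
for name, size, spacing in cases:
    geom = ImageGeometry(size=size, spacing=spacing,
                         origin=(0.0,) * len(size))
    trigger = needs_resampling(geom, cfg)
    line = f"{name}: {geom.voxel_count / 1e6:.1f}M voxels, spacing {spacing}"
    if trigger:
        s = target_isotropic_spacing(geom, cfg)
        new = resampled_size(geom, s)
        line += (f" -> resample to {s:.2f} mm isotropic, size {new} "
                 f"({np.prod(new) / 1e6:.1f}M voxels)")
    else:
        line += " -> kept as is"
    print(line)
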