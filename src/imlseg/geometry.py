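"""Image geometry: voxel grid size, spacing, origin, and orientation.

Conventions
-----------
``size``, ``spacing`` and ``origin`` are stored in *array-axis order*: index
0 corresponds to the slowest-varying numpy axis. For a 3D image loaded from
disk this is the reverse of the (x, y, z) order used by ITK; the conversion
happens once at the I/O boundary (see :mod:`imlseg.imageio`). ``direction``
is the orientation matrix exactly as the file header stores it (row-major,
ITK convention); it is carried through unchanged and compared for equality
across co-registered inputs, never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Header floats of co-registered series differ by rounding noise; these
# tolerances accept that noise and nothing more.
SPACING_RTOL = 1e-4
ORIGIN_ATOL_MM = 1e-3


@dataclass(frozen=True)
class ImageGeometry:
    """Voxel grid geometry of a scalar image.

    Parameters
    ----------
    size : tuple of int
        Grid extent in voxels per dimension, array-axis order.
    spacing : tuple of float
        Physical voxel size in mm per dimension, array-axis order.
    origin : tuple of float
        Physical position of voxel (0, ..., 0) in mm, array-axis order.
    direction : tuple of float
        Flattened orientation matrix in the on-disk (ITK) convention.
        Defaults to identity.
    """

    size: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]
    direction: tuple[float, ...] = field(default=())

    def __post_init__(self):
        size = tuple(int(s) for s in self.size)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        ndim = len(size)
        if ndim not in (2, 3):
            raise ValueError(f"only 2D and 3D grids are supported, got {ndim}D")
        if len(spacing) != ndim or len(origin) != ndim:
            raise ValueError("size, spacing and origin must have equal length")
        if any(s < 1 for s in size):
            raise ValueError("all size entries must be >= 1")
        if any(s <= 0 for s in spacing):
            raise ValueError("all spacing entries must be > 0")
        direction = tuple(float(d) for d in self.direction)
        if not direction:
            direction = tuple(np.eye(ndim).ravel())
        if len(direction) != ndim * ndim:
            raise ValueError("direction must be a flattened DxD matrix")
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def ndim(self) -> int:
        return len(self.size)

    @property
    def voxel_count(self) -> int:
        return int(np.prod(self.size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def matches(self, other: "ImageGeometry",
                spacing_rtol: float = SPACING_RTOL,
                origin_atol: float = ORIGIN_ATOL_MM) -> bool:
        """Whether two geometries describe the same grid within tolerance.

        Spacing is compared relatively, origin absolutely (mm), size and
        direction exactly — per the co-registration contract.
        """
        if self.size != other.size:
            return False
        if not np.allclose(self.spacing, other.spacing, rtol=spacing_rtol, atol=0.0):
            return False
        if not np.allclose(self.origin, other.origin, rtol=0.0, atol=origin_atol):
            return False
        if len(self.direction) != len(other.direction):
            return False
        return bool(np.allclose(self.direction, other.direction, rtol=0.0, atol=1e-6))
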