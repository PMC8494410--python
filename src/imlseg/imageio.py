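"""Reading and writing medical images (NIfTI, NRRD, MetaImage).

All file traffic goes through SimpleITK. In memory, voxel data are numpy
arrays whose axis order is the reverse of ITK's (x, y, z): this module is
the only place where that conversion happens. Multi-channel input is a list
of single-channel files sharing one grid; co-registration is validated on
load, never performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import (
    CoRegistrationError,
    InputError,
    InsufficientLabelsError,
    UnsupportedFormatError,
)
from .geometry import ImageGeometry


@dataclass(frozen=True)
class MultiChannelImage:
    """C co-registered scalar channels on one voxel grid.

    ``channels`` is an ordered list of float64 arrays; order follows the
    order the files were given in.
    """

    channels: tuple[np.ndarray, ...]
    geometry: ImageGeometry

    def __post_init__(self):
        if len(self.channels) < 1:
            raise ValueError("at least one channel is required")
        for ch in self.channels:
            if ch.shape != self.geometry.size:
                raise ValueError("channel shape does not match geometry size")
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class LabelDrawing:
    """Sparse integer label image: 0 = unlabeled, 1..L = classes.

    The class set includes the background class drawn by the user, so a
    drawing supporting N regions of interest carries N + 1 distinct labels.
    """

    labels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self):
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer-typed")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        if self.labels.shape != self.geometry.size:
            raise ValueError("label shape does not match geometry size")

    @property
    def class_ids(self) -> tuple[int, ...]:
        """Sorted distinct nonzero labels present in the drawing."""
        ids = np.unique(self.labels)
        return tuple(int(i) for i in ids if i != 0)


# ---------------------------------------------------------------------------
# SimpleITK conversion helpers

def to_sitk(array: np.ndarray, geometry: ImageGeometry) -> sitk.Image:
    """Build a SimpleITK image from an array in array-axis order."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(reversed(geometry.spacing)))
    img.SetOrigin(tuple(reversed(geometry.origin)))
    img.SetDirection(geometry.direction)
    return img


def from_sitk(img: sitk.Image) -> tuple[np.ndarray, ImageGeometry]:
    """Extract (array, geometry) from a SimpleITK image, reversing axis order."""
    array = sitk.GetArrayFromImage(img)
    geom = ImageGeometry(
        size=tuple(reversed(img.GetSize())),
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
        direction=tuple(img.GetDirection()),
    )
    return array, geom


def _read_scalar(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad files
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise UnsupportedFormatError(
            f"{path}: vector-valued pixel type is not supported")
    # Squeeze a 3D file with a singleton dimension to native 2D.
    if img.GetDimension() == 3 and 1 in img.GetSize():
        arr, geom = from_sitk(img)
        keep = [d for d in range(3) if geom.size[d] > 1]
        if len(keep) == 2:
            arr2 = np.squeeze(arr)
            geom2 = ImageGeometry(
                size=tuple(geom.size[d] for d in keep),
                spacing=tuple(geom.spacing[d] for d in keep),
                origin=tuple(geom.origin[d] for d in keep),
            )
            return to_sitk(arr2, geom2)
    if img.GetDimension() not in (2, 3):
        raise UnsupportedFormatError(
            f"{path}: only 2D and 3D images are supported")
    return img


def load_image_set(paths: list[str]) -> MultiChannelImage:
    """Load co-registered channels from one or more scalar image files.

    Channel order follows ``paths``; the grid geometry is taken from the
    first file and every other file must agree with it within tolerance
    (relative 1e-4 on spacing, 1e-3 mm on origin, exact on size and
    orientation).
    """
    if not paths:
        raise InputError("no input image paths given")
    channels: list[np.ndarray] = []
    geometry: ImageGeometry | None = None
    for path in paths:
        arr, geom = from_sitk(_read_scalar(str(path)))
        if geometry is None:
            geometry = geom
        elif not geometry.matches(geom):
            raise CoRegistrationError(
                f"{path} is not on the grid of {paths[0]}: "
                f"{geom} vs {geometry}")
        channels.append(arr.astype(np.float64))
    assert geometry is not None
    return MultiChannelImage(channels=tuple(channels), geometry=geometry)


def load_drawing(path: str, geometry: ImageGeometry) -> LabelDrawing:
    """Load a sparse label drawing and validate it against ``geometry``."""
    arr, geom = from_sitk(_read_scalar(str(path)))
    if not geometry.matches(geom):
        raise CoRegistrationError(
            f"label drawing {path} is not on the image grid")
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise InputError(f"{path}: label image has non-integer values")
        arr = rounded
    labels = arr.astype(np.int32)
    drawing = LabelDrawing(labels=labels, geometry=geom)
    if len(drawing.class_ids) < 2:
        raise InsufficientLabelsError(
            f"{path}: a drawing needs at least 2 distinct nonzero labels "
            f"(N regions + background), found {list(drawing.class_ids)}")
    return drawing


def save_label_image(labels: np.ndarray, geometry: ImageGeometry,
                     path: str) -> None:
    """Write an integer label image; round-trips exactly through load."""
    if not np.issubdtype(labels.dtype, np.integer):
        raise InputError("label array must be integer-typed before saving")
    img = to_sitk(labels.astype(np.int32), geometry)
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def save_scalar_image(array: np.ndarray, geometry: ImageGeometry,
                      path: str) -> None:
    """Write a scalar (float) image, e.g. a geodesic distance map."""
    img = to_sitk(np.asarray(array, dtype=np.float32), geometry)
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
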