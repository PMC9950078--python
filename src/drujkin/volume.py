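"""Image volumes on regular 3D grids, with NIfTI / MetaImage I/O.

Arrays are indexed ``[z, y, x]`` (axis 0 longitudinal); ``spacing`` and
``origin`` are stored in the same (z, y, x) order, in mm.  ``origin`` is the
world coordinate of the *center* of voxel (0, 0, 0).  SimpleITK stores
spacing/origin in (x, y, z) order, so I/O reverses the metadata but never the
voxel array.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

__all__ = ["Volume", "GridSpec", "read_volume", "write_volume"]


@dataclass(frozen=True)
class GridSpec:
    """Shape/spacing/origin of a sampling grid, in (z, y, x) order."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centers, C-ordered."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)

    def extent(self) -> np.ndarray:
        """(2, 3) [min; max] world coordinates of voxel centers."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi])


@dataclass(frozen=True)
class Volume:
    """A scalar field sampled on a regular grid.

    ``data`` may be float (images, level sets) or bool (masks).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"volume array must be 3D, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if arr.dtype != bool and not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (n, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_from_index(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=float))
        return i * np.asarray(self.spacing) + np.asarray(self.origin)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points whose trilinear support is inside the grid."""
        idx = self.index_from_world(points)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx <= shape - 1), axis=1)

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world points (n, 3) -> (n,) values."""
        idx = self.index_from_world(points)
        return map_coordinates(
            self.data.astype(float, copy=False),
            idx.T,
            order=order,
            mode="constant",
            cval=cval,
        )

    # -- I/O ---------------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        arr = self.data
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img)
        return cls(arr, tuple(img.GetSpacing()[::-1]), tuple(img.GetOrigin()[::-1]))

    def save(self, path: str | os.PathLike) -> None:
        write_volume(self, path)


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha); format by suffix."""
    sitk.WriteImage(vol.to_sitk(), os.fspath(path))


def read_volume(path: str | os.PathLike) -> Volume:
    return Volume.from_sitk(sitk.ReadImage(os.fspath(path)))
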