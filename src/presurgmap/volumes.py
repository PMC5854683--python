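"""Core in-memory containers for volumetric fMRI data.

All volumes carry a voxel-to-world affine in RAS+ millimetres (NIfTI
convention).  Voxel indices are 0-based; world coordinates are obtained as
``affine @ [i, j, k, 1]``.  Data read from DICOM (LPS) is converted to RAS+
on import and back to LPS on export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "Volume4D",
    "StatMap",
    "MaskVolume",
    "RigidTransform",
    "GeometryError",
    "load_volume3d",
    "load_volume4d",
    "save_volume",
    "voxel_sizes",
]


class GeometryError(ValueError):
    """Raised when affines or grids are inconsistent or degenerate."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular")
    return affine


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm along each array axis."""
    return np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume3D:
    """A 3D scalar volume with a RAS+ voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)


@dataclass
class Volume4D:
    """A 4D BOLD time series (x, y, z, t) with TR and optional slice times.

    Parameters
    ----------
    data : ndarray
        4D array, last axis is time.
    affine : ndarray
        4x4 RAS+ voxel-to-world map of the spatial grid.
    tr : float
        Repetition time in seconds; must be positive.
    slice_times : ndarray, optional
        Per-slice acquisition offsets in seconds, length equal to the
        z-dimension.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    slice_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one timepoint")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.affine = _check_affine(self.affine)
        if self.slice_times is not None:
            self.slice_times = np.asarray(self.slice_times, dtype=float)
            if self.slice_times.shape != (self.data.shape[2],):
                raise ValueError(
                    "slice_times length must equal number of slices "
                    f"({self.slice_times.size} != {self.data.shape[2]})"
                )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.data[..., t], self.affine)


#: statistic kinds a StatMap may carry
STAT_TYPES = ("t", "z", "r", "reho", "cvr_t")


@dataclass
class StatMap:
    """A 3D statistic volume (t, Fisher z, r, ReHo W, or CVR max-t)."""

    data: np.ndarray
    affine: np.ndarray
    stat_type: str
    df: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        self.affine = _check_affine(self.affine)
        if self.stat_type not in STAT_TYPES:
            raise ValueError(f"unknown stat_type {self.stat_type!r}")
        if self.stat_type == "t" and self.df is None:
            raise ValueError("t maps require degrees of freedom")


@dataclass
class MaskVolume:
    """A binary 3D mask; values are exactly 0 or 1."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3D")
        self.data = (arr > 0).astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "MaskVolume") -> "MaskVolume":
        return MaskVolume(self.data & other.data, self.affine)


def _rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 homogeneous matrix from (rx, ry, rz) radians and (tx, ty, tz) mm.

    Rotations are applied in x-then-y-then-z order about the world origin.
    """
    rx, ry, rz, tx, ty, tz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    mat = np.eye(4)
    mat[:3, :3] = Rz @ Ry @ Rx
    mat[:3, 3] = (tx, ty, tz)
    return mat


@dataclass
class RigidTransform:
    """A 6-parameter rigid-body world-space transform.

    ``params`` is (rx, ry, rz, tx, ty, tz): rotations in radians, then
    translations in mm.  ``matrix`` is the equivalent 4x4 homogeneous map.
    """

    params: np.ndarray
    matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (6,):
            raise ValueError("rigid transform needs exactly 6 parameters")
        if self.matrix is None:
            self.matrix = _rigid_matrix(self.params)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        rot = self.matrix[:3, :3]
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("rotation block must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(6))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        mat = self.matrix @ other.matrix
        rot = mat[:3, :3]
        # recover Euler angles (x-y-z convention) for the params field
        ry = np.arcsin(np.clip(-rot[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-8:
            rx = np.arctan2(rot[2, 1], rot[2, 2])
            rz = np.arctan2(rot[1, 0], rot[0, 0])
        else:  # gimbal lock; absorb into rx
            rx = np.arctan2(-rot[1, 2], rot[1, 1])
            rz = 0.0
        params = np.array([rx, ry, rz, *mat[:3, 3]])
        return RigidTransform(params, mat)

    def inverse(self) -> "RigidTransform":
        mat = np.linalg.inv(self.matrix)
        rot = mat[:3, :3]
        ry = np.arcsin(np.clip(-rot[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-8:
            rx = np.arctan2(rot[2, 1], rot[2, 2])
            rz = np.arctan2(rot[1, 0], rot[0, 0])
        else:
            rx = np.arctan2(-rot[1, 2], rot[1, 1])
            rz = 0.0
        return RigidTransform(np.array([rx, ry, rz, *mat[:3, 3]]), mat)


# ---------------------------------------------------------------------------
# NIfTI round-tripping via nibabel

def load_volume3d(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume3D(data, img.affine)


def load_volume4d(path, tr: float | None = None,
                  slice_times=None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError("TR not recoverable from header; pass tr explicitly")
    return Volume4D(data, img.affine, tr, slice_times)


def save_volume(vol, path) -> None:
    """Write a Volume3D/Volume4D/StatMap/MaskVolume as NIfTI-1."""
    data = np.asarray(vol.data)
    img = nib.Nifti1Image(data.astype(np.float32), vol.affine)
    tr = getattr(vol, "tr", None)
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))
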