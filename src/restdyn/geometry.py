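"""Volume geometry and the basic on-grid containers.

All volumetric data in this package live on a regular, axis-aligned 3D
grid.  Axis 0 is the left-right axis: voxel indices below the mid-sagittal
plane are the *left* hemisphere (where lesions are planted), indices above
it the right.  The mid-sagittal plane sits at index ``(shape[0] - 1) / 2``,
so the grid is always symmetric under reflection — a requirement for
constructing contralesional mirror ROIs with exactly matched voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "BinaryMask", "VolumeMap"]

LR_AXIS = 0


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and physical voxel size of a regular 3D grid.

    Parameters
    ----------
    shape
        Voxels per axis, all strictly positive.
    voxel_size
        Edge length of a voxel along each axis in mm (anisotropic allowed).
    midline_index
        Position of the mid-sagittal plane along axis 0, in (fractional)
        voxel units.  Defaults to ``(shape[0] - 1) / 2`` which is the only
        value for which index reflection maps the grid onto itself.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0)
    midline_index: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        if any(s <= 0 for s in shape):
            raise ValueError(f"shape must be strictly positive, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be > 0, got {vs}")
        mid = self.midline_index
        if mid is None:
            mid = (shape[LR_AXIS] - 1) / 2.0
        mid = float(mid)
        if not np.isclose(2.0 * mid, shape[LR_AXIS] - 1):
            raise ValueError(
                "grid is not symmetric about midline_index "
                f"{mid} along the left-right axis (shape {shape[LR_AXIS]})"
            )
        object.__setattr__(self, "midline_index", mid)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate grids (mm) of voxel centers, one array per axis."""
        axes = [np.arange(s) * v for s, v in zip(self.shape, self.voxel_size)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def is_left(self) -> np.ndarray:
        """Boolean volume: voxels strictly left of the mid-sagittal plane."""
        idx = np.arange(self.shape[LR_AXIS], dtype=float)
        half = idx < self.midline_index
        shape = [1, 1, 1]
        shape[LR_AXIS] = -1
        return np.broadcast_to(half.reshape(shape), self.shape).copy()

    def is_right(self) -> np.ndarray:
        idx = np.arange(self.shape[LR_AXIS], dtype=float)
        half = idx > self.midline_index
        shape = [1, 1, 1]
        shape[LR_AXIS] = -1
        return np.broadcast_to(half.reshape(shape), self.shape).copy()


def _check_shape(data: np.ndarray, geometry: VolumeGeometry) -> None:
    if tuple(data.shape) != tuple(geometry.shape):
        raise ValueError(
            f"data shape {data.shape} does not match geometry {geometry.shape}"
        )


@dataclass(frozen=True)
class BinaryMask:
    """0/1 values on a :class:`VolumeGeometry`."""

    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        data = data.astype(bool)
        _check_shape(data, self.geometry)
        object.__setattr__(self, "data", data)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(k, 3) integer voxel indices of set voxels, C order."""
        return np.argwhere(self.data)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_geometry(self, other)
        return BinaryMask(self.data & other.data, self.geometry)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_geometry(self, other)
        return BinaryMask(self.data | other.data, self.geometry)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_geometry(self, other)
        return BinaryMask(self.data & ~other.data, self.geometry)


@dataclass(frozen=True)
class VolumeMap:
    """Scalar values on a :class:`VolumeGeometry`; NaN marks missing data."""

    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        _check_shape(data, self.geometry)
        object.__setattr__(self, "data", data)

    def mean_in(self, mask: BinaryMask) -> float:
        """Mean over in-mask voxels, ignoring NaN; NaN for an empty mask."""
        _require_same_geometry(self, mask)
        vals = self.data[mask.data]
        if vals.size == 0:
            return float("nan")
        return float(np.nanmean(vals))


def _require_same_geometry(a, b) -> None:
    if a.geometry != b.geometry:
        raise ValueError("operands are on different volume geometries")
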