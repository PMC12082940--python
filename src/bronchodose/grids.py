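"""Geometry-aware voxel volumes and binary structure masks.

Everything downstream (structure derivation, dose metrics, motion analysis)
is built on three containers defined here:

``VoxelGrid``
    An axis-aligned lattice in the DICOM patient coordinate system
    (x: right→left, y: anterior→posterior, z: inferior→superior), described
    by an origin (mm), per-axis spacing (mm/voxel) and dimensions. Arrays are
    indexed ``[ix, iy, iz]`` and world coordinates are the exchange currency
    between modules; indices are 0-based and never cross a module boundary.

``ScalarVolume``
    A scalar field (CT in HU, or dose in % of the prescribed dose) on a grid.

``StructureMask``
    A named binary region on a grid. Voxel membership is decided by the
    voxel-centre test, so volumes are exact voxel counts times voxel volume.

Masks never resample silently: any operation combining two masks requires
identical grids and raises ``GridMismatchError`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "StructureMask",
    "GridMismatchError",
    "OutOfExtentError",
    "resample_volume",
    "expand_mask",
    "boolean_combine",
    "sample_at_point",
    "sphere_mask",
    "CT_FILL_HU",
    "DOSE_FILL_PCT",
]

#: Out-of-extent fill values: air for CT, zero for relative dose.
CT_FILL_HU = -1000.0
DOSE_FILL_PCT = 0.0


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


class OutOfExtentError(ValueError):
    """A world point lies outside the volume extent."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in DICOM patient coordinates (mm)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        """Continuous index -> world mm. Accepts (..., 3) arrays."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def index_from_world(self, point_mm: np.ndarray) -> np.ndarray:
        """World mm -> continuous index. Accepts (..., 3) arrays."""
        point_mm = np.asarray(point_mm, dtype=float)
        return (point_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_point(self, point_mm) -> bool:
        """True if the point lies within the lattice hull (voxel centres)."""
        idx = self.index_from_world(point_mm)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.dims) - 1))

    def centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (*dims, 3)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class ScalarVolume:
    """Scalar field on a :class:`VoxelGrid`.

    ``kind`` is ``"HU"`` for CT volumes or ``"dose"`` for relative dose in
    percent of the prescribed dose (``prescribed_dose_gy`` carries the
    absolute scale when known).
    """

    grid: VoxelGrid
    values: np.ndarray
    kind: Literal["HU", "dose"] = "HU"
    prescribed_dose_gy: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.kind == "dose" and np.any(self.values < 0):
            raise ValueError("relative dose must be non-negative")

    @property
    def fill_value(self) -> float:
        return CT_FILL_HU if self.kind == "HU" else DOSE_FILL_PCT

    def copy_with(self, **kw) -> "ScalarVolume":
        return replace(self, **kw)


@dataclass
class StructureMask:
    """Named binary region on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    membership: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.membership.shape} != grid dims {self.grid.dims}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.membership.sum()) * self.grid.voxel_volume_cc

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())

    def is_empty(self) -> bool:
        return not self.membership.any()

    def centers_mm(self) -> np.ndarray:
        """World coordinates of member voxel centres, shape (n, 3)."""
        idx = np.argwhere(self.membership)
        return self.grid.world_from_index(idx)

    def with_name(self, name: str) -> "StructureMask":
        return StructureMask(self.grid, self.membership, name)


def _require_same_grid(a, b, what: str = "operands") -> None:
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError(f"{what} are on different grids; resample explicitly")


def resample_volume(
    vol: ScalarVolume,
    target: VoxelGrid,
    interp: Literal["nearest", "trilinear"] = "trilinear",
    fill_value: float | None = None,
) -> ScalarVolume:
    """Resample a scalar volume onto another grid.

    Voxels of ``target`` whose centres fall outside the extent of ``vol``
    take ``fill_value`` (default: −1000 HU for CT, 0 % for dose).
    """
    if interp not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    fill = vol.fill_value if fill_value is None else float(fill_value)
    centers = target.centers_mm().reshape(-1, 3)
    out = _sample_points(vol, centers, interp, fill).reshape(target.dims)
    return ScalarVolume(target, out, kind=vol.kind,
                        prescribed_dose_gy=vol.prescribed_dose_gy)


def _sample_points(
    vol: ScalarVolume, points_mm: np.ndarray, interp: str, fill: float
) -> np.ndarray:
    """Sample the volume at world points (n, 3) with out-of-extent fill."""
    idx = vol.grid.index_from_world(points_mm)
    order = 0 if interp == "nearest" else 1
    coords = idx.T  # map_coordinates wants (3, n)
    out = ndimage.map_coordinates(
        vol.values, coords, order=order, mode="constant", cval=fill, prefilter=False
    )
    # map_coordinates pads with cval only beyond the half-voxel border in
    # nearest mode; enforce the voxel-centre hull as the extent in both modes
    dims = np.asarray(vol.grid.dims)
    inside = np.all((idx >= 0) & (idx <= dims - 1), axis=-1)
    out = np.where(inside, out, fill)
    return out


def sample_at_point(
    vol: ScalarVolume,
    point_mm,
    interp: Literal["nearest", "trilinear"] = "trilinear",
) -> float:
    """Sample the volume at one world point; raises outside the extent."""
    point_mm = np.asarray(point_mm, dtype=float)
    if not vol.grid.contains_point(point_mm):
        raise OutOfExtentError(f"point {point_mm.tolist()} outside volume extent")
    return float(_sample_points(vol, point_mm[None, :], interp, vol.fill_value)[0])


def expand_mask(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic Euclidean dilation by ``margin_mm`` in world space.

    The output contains every voxel whose centre lies within ``margin_mm``
    of the input voxel-centre set, so the operation is extensive
    (input ⊆ output) and monotone in the margin.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty():
        return StructureMask(mask.grid, mask.membership.copy(), mask.name)
    dist = ndimage.distance_transform_edt(
        ~mask.membership, sampling=mask.grid.spacing
    )
    return StructureMask(mask.grid, dist <= margin_mm + 1e-9, mask.name)


def boolean_combine(
    a: StructureMask,
    b: StructureMask,
    op: Literal["union", "intersect", "subtract"],
    name: str = "",
) -> StructureMask:
    """Voxelwise set operation on two masks sharing a grid."""
    _require_same_grid(a, b, "masks")
    if op == "union":
        out = a.membership | b.membership
    elif op == "intersect":
        out = a.membership & b.membership
    elif op == "subtract":
        out = a.membership & ~b.membership
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return StructureMask(a.grid, out, name or f"{a.name}_{op}_{b.name}")


def sphere_mask(
    grid: VoxelGrid, centre_mm, radius_mm: float, name: str = "sphere"
) -> StructureMask:
    """Voxels whose centres lie within ``radius_mm`` of ``centre_mm``.

    For radii below half the largest spacing the nearest voxel is included
    anyway, so the sphere is never empty.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    centre_mm = np.asarray(centre_mm, dtype=float)
    if not grid.contains_point(centre_mm):
        raise ValueError(f"sphere centre {centre_mm.tolist()} outside grid extent")
    d2 = np.sum((grid.centers_mm() - centre_mm) ** 2, axis=-1)
    member = d2 <= radius_mm**2 + 1e-9
    if not member.any():
        nearest = np.unravel_index(np.argmin(d2), grid.dims)
        member[nearest] = True
    return StructureMask(grid, member, name)
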