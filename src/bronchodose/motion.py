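"""Geometric change metrics between source and subsequent CT, dose warping
and multi-fraction dose accumulation.

The rigid residual shift of the bronchial tree (‖CBTree‖) is the difference
between a contour-based rigid alignment of the tree and the clinical
image-guidance registration; deformable motion is read off deformation
vector fields (DVFs), which are *inputs* here — no deformable registration
is implemented. Dose accumulation averages per-fraction relative doses, so
accumulated values stay on the percent-of-prescription scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import (
    GridMismatchError,
    OutOfExtentError,
    ScalarVolume,
    StructureMask,
    VoxelGrid,
    sphere_mask,
)
from .dosimetry import DoseStudy

__all__ = [
    "RigidTransform",
    "DeformationField",
    "ShiftMetrics",
    "rigid_align_masks",
    "residual_shift",
    "dvf_shift_at_dmax",
    "mean_distance_to_agreement",
    "hausdorff_to_v10",
    "warp_dose",
    "accumulate_fractions",
    "dmax_position_dispersion",
    "surface_voxels",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map x ↦ R·x + t in patient millimetre coordinates."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", tuple(map(tuple, R)))
        object.__setattr__(
            self, "translation", tuple(float(v) for v in self.translation)
        )

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.matrix.T
        t = -R @ np.asarray(self.translation)
        return RigidTransform(tuple(t), tuple(map(tuple, R)))


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) mapping points of one space into another.

    ``direction`` is a ``(from_space, to_space)`` pair; a point x in
    *from_space* maps to ``x + u(x)`` in *to_space*. The flag is mandatory
    so a field is never applied backwards silently.
    """

    grid: VoxelGrid
    displacement: np.ndarray
    direction: tuple[str, str]

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != (*self.grid.dims, 3):
            raise ValueError("displacement must have shape (*dims, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field must be finite")
        if len(self.direction) != 2:
            raise ValueError("direction must be a (from, to) pair")
        self.direction = (str(self.direction[0]), str(self.direction[1]))

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear displacement at world points (n, 3)."""
        idx = self.grid.index_from_world(np.atleast_2d(points_mm))
        out = np.stack(
            [
                ndimage.map_coordinates(
                    self.displacement[..., c], idx.T, order=1,
                    mode="nearest", prefilter=False,
                )
                for c in range(3)
            ],
            axis=-1,
        )
        return out


@dataclass
class ShiftMetrics:
    cbtree_shift_mm: tuple[float, float, float]
    cbtree_norm_mm: float
    shift_at_dmax_mm: float | None = None
    mda_mm: float | None = None
    hausdorff_to_v10_mm: float | None = None


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """World coordinates (n, 3) of surface voxel centres (6-connectivity)."""
    interior = ndimage.binary_erosion(mask.membership)
    surf = mask.membership & ~interior
    return mask.grid.world_from_index(np.argwhere(surf))


def _best_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired src onto dst (Kabsch)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cd - R @ cs
    return RigidTransform(tuple(t), tuple(map(tuple, R)))


def _signed_distance_field(mask: StructureMask) -> np.ndarray:
    out = ndimage.distance_transform_edt(~mask.membership,
                                         sampling=mask.grid.spacing)
    inn = ndimage.distance_transform_edt(mask.membership,
                                         sampling=mask.grid.spacing)
    return out - inn


def _sample_field(field: np.ndarray, grid: VoxelGrid,
                  pts_mm: np.ndarray) -> np.ndarray:
    idx = grid.index_from_world(pts_mm).T
    return ndimage.map_coordinates(field, idx, order=1, mode="nearest",
                                   prefilter=False)


def rigid_align_masks(
    moving: StructureMask,
    fixed: StructureMask,
    max_iter: int = 50,
    tol_mm: float = 1e-4,
) -> RigidTransform:
    """Contour-based rigid alignment of two masks (iterative closest surface).

    Surface voxel centres of the moving mask are driven onto the zero level
    of the fixed mask's signed-distance field: translation-first
    initialization by the centroid difference, then Gauss–Newton steps on
    the mean squared surface distance to a local optimum. Matching the
    implicit surface rather than discrete surface voxels avoids the
    correspondence bias of plain point-to-point ICP on voxelized contours.
    Deterministic — no random restarts.
    """
    p_mov = surface_voxels(moving)
    p_fix = surface_voxels(fixed)
    if len(p_mov) < 10 or len(p_fix) < 10:
        raise ValueError("masks too small for contour alignment (<10 surface voxels)")
    if moving.grid.same_geometry(fixed.grid) and np.array_equal(
        moving.membership, fixed.membership
    ):
        return RigidTransform()  # identical contours: identity is exact
    sdf = _signed_distance_field(fixed)
    grid = fixed.grid
    grads = np.gradient(sdf, *grid.spacing)
    centre = p_mov.mean(axis=0)

    t = p_fix.mean(axis=0) - centre
    R = np.eye(3)
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = (p_mov - centre) @ R.T + centre + t
        r = _sample_field(sdf, grid, moved)
        rms = float(np.sqrt(np.mean(r**2)))
        if abs(prev_rms - rms) < tol_mm:
            break
        prev_rms = rms
        g = np.stack([_sample_field(c, grid, moved) for c in grads], axis=-1)
        lever = moved - centre
        # d sd / d(t, ω) with rotation updated as R ← exp([ω]×) R
        J = np.hstack([g, np.cross(lever, g)])
        delta, *_ = np.linalg.lstsq(J, -r, rcond=None)
        t = t + delta[:3]
        w = delta[3:]
        angle = np.linalg.norm(w)
        if angle > 1e-12:
            k = w / angle
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            R_delta = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
            R = R_delta @ R
    # convert the centred parametrization to x ↦ R x + t_world
    t_world = centre + t - R @ centre
    U, _, Vt = np.linalg.svd(R)  # re-orthonormalize accumulated rotation
    R = U @ Vt
    return RigidTransform(tuple(t_world), tuple(map(tuple, R)))


def residual_shift(
    contour_alignment: RigidTransform, clinical_registration: RigidTransform
) -> tuple[tuple[float, float, float], float]:
    """Residual tree shift after image guidance: contour minus clinical
    translation, per DICOM axis, plus its Euclidean norm (‖CBTree‖)."""
    d = np.asarray(contour_alignment.translation) - np.asarray(
        clinical_registration.translation
    )
    return tuple(float(v) for v in d), float(np.linalg.norm(d))


def dvf_shift_at_dmax(
    dvf: DeformationField, dmax_point_mm, radius_mm: float = 1.0
) -> float:
    """Mean displacement-vector length over a small sphere at the hotspot.

    Samples the field on the voxels of a 1-mm-radius sphere around the Dmax
    point of the subsequent CT's wall hotspot.
    """
    point = np.asarray(dmax_point_mm, dtype=float)
    if not dvf.grid.contains_point(point):
        raise OutOfExtentError(f"point {point.tolist()} outside DVF extent")
    sph = sphere_mask(dvf.grid, point, radius_mm)
    lengths = np.linalg.norm(dvf.displacement[sph.membership], axis=-1)
    return float(lengths.mean())


def mean_distance_to_agreement(
    surface_a: StructureMask, surface_b: StructureMask
) -> float:
    """Symmetric MDA: average of both directed mean nearest-surface distances."""
    if surface_a.is_empty() or surface_b.is_empty():
        raise ValueError("MDA requires two non-empty masks")
    pa, pb = surface_voxels(surface_a), surface_voxels(surface_b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def hausdorff_to_v10(dmax_point_backdeformed, v10: StructureMask) -> float | None:
    """Distance from the back-deformed hotspot to the nearest V10 voxel.

    Directed point-to-set distance: 0 when the point lies inside V10 and
    ``None`` (with a warning) when V10 is empty — a missing value, not an
    error, since robust plans can have an empty sensitivity volume.
    """
    if v10.is_empty():
        warnings.warn("V10 is empty; Hausdorff distance undefined", stacklevel=2)
        return None
    point = np.asarray(dmax_point_backdeformed, dtype=float)
    idx = v10.grid.index_from_world(point)
    nearest_vox = np.clip(np.round(idx), 0, np.asarray(v10.grid.dims) - 1).astype(int)
    if v10.membership[tuple(nearest_vox)]:
        return 0.0
    centers = v10.centers_mm()
    return float(np.min(np.linalg.norm(centers - point, axis=1)))


def warp_dose(
    dose: DoseStudy,
    dvf: DeformationField,
    target: VoxelGrid,
    dose_space: str | None = None,
) -> DoseStudy:
    """Pull-back warp of a dose volume onto ``target``.

    The field must map target-space points into the dose's space
    (``dvf.direction[1]`` names that space when ``dose_space`` is given);
    each target voxel centre x samples the dose trilinearly at x + u(x).
    """
    if dose_space is not None and dvf.direction[1] != dose_space:
        raise ValueError(
            f"DVF maps {dvf.direction[0]}→{dvf.direction[1]}, "
            f"but the dose lives in {dose_space!r}"
        )
    pts = target.centers_mm().reshape(-1, 3)
    src_pts = pts + dvf.sample(pts)
    idx = dose.grid.index_from_world(src_pts)
    vals = ndimage.map_coordinates(
        dose.dose.values, idx.T, order=1, mode="constant", cval=0.0, prefilter=False
    )
    dims = np.asarray(dose.grid.dims)
    inside = np.all((idx >= 0) & (idx <= dims - 1), axis=1)
    vals = np.where(inside, vals, 0.0).reshape(target.dims)
    warped = ScalarVolume(target, np.maximum(vals, 0.0), kind="dose",
                          prescribed_dose_gy=dose.dose.prescribed_dose_gy)
    return DoseStudy(warped, dose.ct_label, dose.plan_label, dose.wor)


def accumulate_fractions(mapped_doses: list[DoseStudy]) -> DoseStudy:
    """Voxelwise mean of per-fraction relative doses on a common grid.

    Averaging keeps the accumulated distribution in percent of the total
    prescription, so hotspots that wander from fraction to fraction
    accumulate to less than the mean of the per-fraction maxima.
    """
    if not mapped_doses:
        raise ValueError("need at least one dose to accumulate")
    grid = mapped_doses[0].grid
    for d in mapped_doses[1:]:
        if not d.grid.same_geometry(grid):
            raise GridMismatchError("accumulation requires a common grid")
    mean = np.mean([d.dose.values for d in mapped_doses], axis=0)
    vol = ScalarVolume(grid, mean, kind="dose",
                       prescribed_dose_gy=mapped_doses[0].dose.prescribed_dose_gy)
    first = mapped_doses[0]
    return DoseStudy(vol, first.ct_label, first.plan_label, first.wor)


def dmax_position_dispersion(points_mm: list) -> float:
    """Mean Euclidean deviation of hotspot positions from their centroid."""
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("dispersion needs at least two points")
    centroid = pts.mean(axis=0)
    return float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
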