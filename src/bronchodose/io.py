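"""Readers and writers for volumes, masks, transforms and case manifests.

The internal representation is format-agnostic (:mod:`bronchodose.grids`);
this module maps it onto

* NIfTI (``.nii``/``.nii.gz``) for scalar volumes, masks and 3-component
  deformation fields, with an axis-aligned affine whose translation is the
  grid origin — coordinates are interpreted as DICOM patient millimetres
  throughout the package and are written to NIfTI verbatim;
* DICOM RT Dose (dose-grid scaling applied) and RT Structure Sets (contours
  rasterized slice-wise with an even–odd voxel-centre rule);
* a JSON manifest per case listing the CT volumes, masks and transforms of
  one fraction, and JSON files for rigid transforms.

Synthetic studies never touch DICOM; the DICOM path exists for clinical use.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import ScalarVolume, StructureMask, VoxelGrid

__all__ = [
    "write_nifti_volume",
    "read_nifti_volume",
    "write_nifti_mask",
    "read_nifti_mask",
    "write_manifest",
    "read_manifest",
    "read_rtdose",
    "read_ct_series",
    "rasterize_rtstruct",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> VoxelGrid:
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = np.abs(np.diag(lin))
    return VoxelGrid(tuple(aff[:3, 3]), tuple(spacing), tuple(shape[:3]))


def write_nifti_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.grid))
    img.header["descrip"] = vol.kind.encode()[:80]
    nib.save(img, str(path))


def read_nifti_volume(path, kind: str = "HU",
                      prescribed_dose_gy: float | None = None) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = _grid_from_affine(img.affine, data.shape)
    return ScalarVolume(grid, data, kind=kind, prescribed_dose_gy=prescribed_dose_gy)


def write_nifti_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def read_nifti_mask(path, name: str = "") -> StructureMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    grid = _grid_from_affine(img.affine, data.shape)
    return StructureMask(grid, data, name or Path(str(path)).stem)


def write_manifest(path, *, volumes: dict, masks: dict,
                   transforms: dict | None = None, meta: dict | None = None) -> None:
    """Write a case manifest: relative file names per named volume/mask."""
    payload = {
        "volumes": dict(volumes),
        "masks": dict(masks),
        "transforms": dict(transforms or {}),
        "meta": dict(meta or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def read_rtdose(path, prescribed_dose_gy: float | None = None) -> ScalarVolume:
    """Read a DICOM RT Dose file into a dose volume.

    Dose-grid scaling is applied; if ``prescribed_dose_gy`` is given the
    values are converted to percent of the prescription, otherwise they are
    kept in Gy on the percent field (caller normalizes).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array is (frames, rows, cols) = (z, y, x); internal order is (x, y, z)
    dose_gy = ds.pixel_array.astype(float).transpose(2, 1, 0) * scaling
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    grid = VoxelGrid(origin, (col_sp, row_sp, dz), dose_gy.shape)
    if prescribed_dose_gy:
        values = 100.0 * dose_gy / prescribed_dose_gy
    else:
        values = dose_gy
    return ScalarVolume(grid, values, kind="dose",
                        prescribed_dose_gy=prescribed_dose_gy)


def read_ct_series(paths) -> ScalarVolume:
    """Read a DICOM CT slice series into an HU volume.

    Slices are sorted by their z position; rescale slope/intercept are
    applied so values come out in Hounsfield units. Requires uniform slice
    spacing and axis-aligned orientation.
    """
    import pydicom

    slices = [pydicom.dcmread(str(p)) for p in paths]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    z = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(z)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError("non-uniform slice spacing in CT series")
    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    hu = np.stack(
        [
            s.pixel_array.astype(float) * float(getattr(s, "RescaleSlope", 1.0))
            + float(getattr(s, "RescaleIntercept", 0.0))
            for s in slices
        ],
        axis=-1,
    )  # (rows, cols, z) = (y, x, z); internal order is (x, y, z)
    hu = hu.transpose(1, 0, 2)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    grid = VoxelGrid(origin, (col_sp, row_sp, float(dz[0]) if len(dz) else 1.0),
                     hu.shape)
    return ScalarVolume(grid, hu, kind="HU")


def rasterize_rtstruct(path, grid: VoxelGrid,
                       roi_names: list[str] | None = None) -> dict[str, StructureMask]:
    """Rasterize an RT Structure Set onto ``grid``.

    Each contour polygon is filled by the voxel-centre test and multiple
    contours on one slice are combined by XOR, which implements the even–odd
    rule (holes come out as holes).
    """
    import pydicom
    from skimage.draw import polygon2mask

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in ds.StructureSetROISequence
    }
    out: dict[str, StructureMask] = {}
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), "")
        if roi_names is not None and name not in roi_names:
            continue
        member = np.zeros(grid.dims, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = grid.index_from_world(pts)
            iz = int(round(float(np.mean(idx[:, 2]))))
            if not 0 <= iz < grid.dims[2]:
                continue
            poly = idx[:, :2]  # (ix, iy) continuous indices
            fill = polygon2mask(grid.dims[:2], poly)
            member[:, :, iz] ^= fill
        out[name] = StructureMask(grid, member, name)
    return out
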