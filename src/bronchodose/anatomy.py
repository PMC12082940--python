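"""Derivation of the central-airway structure system from CT and contours.

Starting from a CT volume and two primary contours — the central bronchial
tree (CBT: trachea, main bronchi, intermediate bronchus and lobar bronchi to
their first bifurcation) and the clinical target volume (CTV, contoured
without the air lumen) — this module derives:

* CBAL, the central bronchial air lumen: CBT voxels strictly below −600 HU;
* CBW, the central bronchial wall: CBT with an 8-mm outer margin, minus CBAL;
* cCTV, the central CTV: the CTV within 2 cm of the CBT (the "no-fly zone");
* the CTV-supplement: air-lumen regions enclosed by the CTV, closed per
  axial slice by a chord across the lumen;
* PTVs by three construction methods of decreasing overlap with the lumen:
  method 1 expands the supplement-unified CTV by 5 mm, method 2 expands the
  clinical CTV by 5 mm (it may overlap the lumen), method 3 additionally
  trims lumen voxels farther than 3 mm from the CTV surface.

All margins are Euclidean distances in millimetres; grid mismatches are
rejected rather than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    GridMismatchError,
    ScalarVolume,
    StructureMask,
    boolean_combine,
    expand_mask,
)

__all__ = [
    "AnatomyModel",
    "derive_cbal",
    "derive_cbw",
    "derive_cctv",
    "build_ctv_supplement",
    "build_ptv",
    "derive_anatomy",
    "CBAL_THRESHOLD_HU",
    "CBW_OUTER_MARGIN_MM",
    "CCTV_DISTANCE_MM",
    "PTV_MARGIN_MM",
    "METHOD3_OVERLAP_LIMIT_MM",
]

CBAL_THRESHOLD_HU = -600.0
CBW_OUTER_MARGIN_MM = 8.0
CCTV_DISTANCE_MM = 20.0
PTV_MARGIN_MM = 5.0
METHOD3_OVERLAP_LIMIT_MM = 3.0


@dataclass
class AnatomyModel:
    """The named structure system on one CT.

    Invariants (checked by :meth:`validate`): CBAL ⊆ CBT, CBW ∩ CBAL = ∅,
    CBAL_PTV ⊆ CBAL ∩ PTV, cCTV ⊆ CTV, and the clinical CTV never overlaps
    the air lumen.
    """

    ct: ScalarVolume
    masks: dict[str, StructureMask]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def validate(self) -> None:
        m = {k: v.membership for k, v in self.masks.items()}
        if "CBAL" in m and "CBT" in m:
            assert not (m["CBAL"] & ~m["CBT"]).any(), "CBAL must lie within CBT"
        if "CBW" in m and "CBAL" in m:
            assert not (m["CBW"] & m["CBAL"]).any(), "CBW must exclude CBAL"
        if "cCTV" in m and "CTV" in m:
            assert not (m["cCTV"] & ~m["CTV"]).any(), "cCTV must lie within CTV"
        if "CTV" in m and "CBAL" in m:
            assert not (m["CTV"] & m["CBAL"]).any(), "clinical CTV excludes CBAL"
        for key in ("PTV_m1", "PTV_m2", "PTV_m3"):
            cp = f"CBAL_PTV_{key[-2:]}"
            if cp in m and key in m:
                assert not (m[cp] & ~(m["CBAL"] & m[key])).any()


def derive_cbal(
    ct: ScalarVolume, cbt: StructureMask, threshold_hu: float = CBAL_THRESHOLD_HU
) -> StructureMask:
    """Air lumen: CBT voxels with HU strictly below the threshold (−600)."""
    if not ct.grid.same_geometry(cbt.grid):
        raise GridMismatchError("CT and CBT mask are on different grids")
    member = cbt.membership & (ct.values < threshold_hu)
    return StructureMask(ct.grid, member, "CBAL")


def derive_cbw(
    cbt: StructureMask,
    cbal: StructureMask,
    outer_margin_mm: float = CBW_OUTER_MARGIN_MM,
) -> StructureMask:
    """Bronchial wall: CBT expanded by the outer margin, minus the lumen."""
    if not cbt.grid.same_geometry(cbal.grid):
        raise GridMismatchError("CBT and CBAL are on different grids")
    if (cbal.membership & ~cbt.membership).any():
        raise ValueError("CBAL must be contained in CBT")
    shell = expand_mask(cbt, outer_margin_mm)
    return boolean_combine(shell, cbal, "subtract", name="CBW")


def derive_cctv(
    ctv: StructureMask,
    cbt: StructureMask,
    distance_mm: float = CCTV_DISTANCE_MM,
) -> StructureMask:
    """Central CTV: portion of the CTV within ``distance_mm`` of the CBT."""
    if not ctv.grid.same_geometry(cbt.grid):
        raise GridMismatchError("CTV and CBT are on different grids")
    zone = expand_mask(cbt, distance_mm)
    return boolean_combine(ctv, zone, "intersect", name="cCTV")


def _close_slice_across(ctv2d: np.ndarray, cbal2d: np.ndarray,
                        spacing_xy: tuple[float, float]) -> np.ndarray:
    """Lumen voxels of one axial slice enclosed by the (chord-closed) CTV.

    Two mechanisms, matching how a planner closes the target contour across
    the airway: lumen regions fully surrounded by the CTV (holes of the CTV
    slice), plus lumen regions captured when the CTV's abutting borders are
    closed by a straight chord — realised as a 2D morphological closing with
    a disk wide enough to bridge the lumen.
    """
    if not ctv2d.any() or not cbal2d.any():
        return np.zeros_like(cbal2d)
    # holes: lumen not reachable from the slice border outside the CTV
    enclosed = ndimage.binary_fill_holes(ctv2d) & cbal2d
    # chord closure: bridge CTV borders across the lumen
    nz = np.argwhere(cbal2d)
    span = nz.max(axis=0) - nz.min(axis=0) + 1
    r_vox = int(np.ceil(max(span) / 2.0)) + 1
    if r_vox > 0:
        yy, xx = np.mgrid[-r_vox:r_vox + 1, -r_vox:r_vox + 1]
        disk = xx**2 + yy**2 <= r_vox**2
        closed = ndimage.binary_closing(ctv2d, structure=disk)
        closed = ndimage.binary_fill_holes(closed)
        enclosed |= closed & cbal2d
    return enclosed


def build_ctv_supplement(
    ctv: StructureMask, cbal: StructureMask
) -> tuple[StructureMask, StructureMask]:
    """CTV-supplement within the air lumen and the unified target.

    Returns ``(supplement, unified)`` where ``unified = CTV ∪ supplement``.
    The supplement holds, per axial slice, the lumen voxels enclosed once the
    CTV boundary is closed across the lumen; lumen fully surrounded by the
    CTV is always included, lumen nowhere adjacent to the CTV never is.
    """
    if not ctv.grid.same_geometry(cbal.grid):
        raise GridMismatchError("CTV and CBAL are on different grids")
    if (ctv.membership & cbal.membership).any():
        raise ValueError("clinical CTV must not overlap CBAL")
    supp = np.zeros(ctv.grid.dims, dtype=bool)
    sx, sy = ctv.grid.spacing[:2]
    for iz in range(ctv.grid.dims[2]):
        c2, a2 = ctv.membership[:, :, iz], cbal.membership[:, :, iz]
        if c2.any() and a2.any():
            # only lumen components touching or near the CTV can be captured
            supp[:, :, iz] = _close_slice_across(c2, a2, (sx, sy))
    supplement = StructureMask(ctv.grid, supp, "CTV_supplement")
    unified = StructureMask(ctv.grid, ctv.membership | supp, "CTV_unified")
    return supplement, unified


def build_ptv(
    ctv_like: StructureMask,
    method: int,
    cbal: StructureMask | None = None,
    margin_mm: float = PTV_MARGIN_MM,
    overlap_limit_mm: float = METHOD3_OVERLAP_LIMIT_MM,
) -> StructureMask:
    """Planning target volume by construction method 1, 2 or 3.

    Method 1 expects the supplement-unified CTV, methods 2/3 the clinical
    CTV. Method 3 removes lumen voxels whose distance from the CTV surface
    exceeds ``overlap_limit_mm`` (3 mm), capping the PTV–lumen overlap.
    """
    if method not in (1, 2, 3):
        raise ValueError(f"unknown PTV method {method!r}")
    ptv = expand_mask(ctv_like, margin_mm)
    if method == 3:
        if cbal is None:
            raise ValueError("method 3 requires the CBAL mask")
        if not ptv.grid.same_geometry(cbal.grid):
            raise GridMismatchError("CTV and CBAL are on different grids")
        dist_to_ctv = ndimage.distance_transform_edt(
            ~ctv_like.membership, sampling=ctv_like.grid.spacing
        )
        too_deep = cbal.membership & (dist_to_ctv > overlap_limit_mm + 1e-9)
        ptv = StructureMask(ptv.grid, ptv.membership & ~too_deep, "")
    return ptv.with_name(f"PTV_m{method}")


def derive_anatomy(
    ct: ScalarVolume,
    cbt: StructureMask,
    ctv: StructureMask,
    methods: tuple[int, ...] = (1, 2, 3),
) -> AnatomyModel:
    """Run the full derivation chain and return a validated AnatomyModel."""
    cbal = derive_cbal(ct, cbt)
    # the clinical CTV is contoured without the air lumen; enforce it so
    # contours propagated onto a deformed CT stay consistent with its HU
    ctv = StructureMask(ctv.grid, ctv.membership & ~cbal.membership, ctv.name)
    cbw = derive_cbw(cbt, cbal)
    cctv = derive_cctv(ctv, cbt)
    masks = {
        "CBT": cbt.with_name("CBT"),
        "CTV": ctv.with_name("CTV"),
        "CBAL": cbal,
        "CBW": cbw,
        "cCTV": cctv,
    }
    prov = {
        "CBAL": "CT < -600 HU within CBT",
        "CBW": "expand(CBT, 8 mm) minus CBAL",
        "cCTV": "CTV within 20 mm of CBT",
    }
    if 1 in methods:
        supplement, unified = build_ctv_supplement(ctv, cbal)
        masks["CTV_supplement"] = supplement
        masks["CTV_unified"] = unified
        masks["PTV_m1"] = build_ptv(unified, 1)
        prov["PTV_m1"] = "expand(CTV ∪ supplement, 5 mm)"
    for m in (2, 3):
        if m in methods:
            masks[f"PTV_m{m}"] = build_ptv(ctv, m, cbal=cbal)
            prov[f"PTV_m{m}"] = f"expand(CTV, 5 mm), method {m}"
    for m in methods:
        key = f"PTV_m{m}"
        if key in masks:
            masks[f"CBAL_PTV_m{m}"] = boolean_combine(
                cbal, masks[key], "intersect", name=f"CBAL_PTV_m{m}"
            )
    model = AnatomyModel(ct, masks, prov)
    model.validate()
    return model
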