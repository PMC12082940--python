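"""Dose-grid metrics: Dmax with location, DVH, D1cc, gEUD, water-override
sensitivity and the gamma pass rate.

All doses are handled in percent of the prescribed dose, the scale on which
plan robustness is reported clinically; absolute Gy lives in volume
metadata. Dmax is a voxel maximum (no sub-voxel interpolation), ties broken
at the lowest (z, y, x) index, which keeps brute-force oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, ScalarVolume, StructureMask

__all__ = [
    "DoseStudy",
    "DVHCurve",
    "DoseMetrics",
    "WORSensitivity",
    "dmax_point",
    "cumulative_dvh",
    "dose_at_volume",
    "geud",
    "delta_dmax",
    "wor_sensitivity",
    "gamma_pass_rate",
    "compute_dose_metrics",
]

CT_LABELS = {"CTplan", "CBCT1", "CBCT2", "synthetic"}
PLAN_LABELS = {"S1", "S2", "S3", "Sclinical", "Adapt", "toy"}


@dataclass
class DoseStudy:
    """One plan's relative-dose volume on a named CT.

    ``wor`` flags a recalculation with the air lumen overridden to water
    density; ``ct_label``/``plan_label`` come from closed vocabularies so a
    sensitivity comparison can verify it pairs like with like.
    """

    dose: ScalarVolume
    ct_label: str = "synthetic"
    plan_label: str = "toy"
    wor: bool = False

    def __post_init__(self) -> None:
        if self.dose.kind != "dose":
            raise ValueError("DoseStudy requires a dose-kind volume")
        if self.ct_label not in CT_LABELS:
            raise ValueError(f"unknown CT label {self.ct_label!r}")
        if self.plan_label not in PLAN_LABELS:
            raise ValueError(f"unknown plan label {self.plan_label!r}")

    @property
    def grid(self):
        return self.dose.grid


@dataclass
class DVHCurve:
    """Cumulative dose–volume histogram: V(d) = volume (cc) receiving ≥ d%."""

    dose_pct: np.ndarray
    volume_cc: np.ndarray

    def __post_init__(self) -> None:
        self.dose_pct = np.asarray(self.dose_pct, dtype=float)
        self.volume_cc = np.asarray(self.volume_cc, dtype=float)
        if np.any(np.diff(self.volume_cc) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])


@dataclass
class DoseMetrics:
    dmax_value: float
    dmax_point_mm: tuple[float, float, float]
    d1cc: float | None
    eud: float | None
    dvh: DVHCurve


@dataclass
class WORSensitivity:
    """Plan-sensitivity score from the water-override comparison.

    ``delta_dmax`` is Dmax(with override) − Dmax(without) inside the
    lumen–PTV overlap; ``v10_mask`` is the lumen subvolume whose dose rises
    by more than the threshold (10 % of prescription) under the override.
    """

    delta_dmax: float
    v10_mask: StructureMask
    v10_cc: float


def _require_mask(dose: ScalarVolume, mask: StructureMask) -> None:
    if not dose.grid.same_geometry(mask.grid):
        raise GridMismatchError("dose and mask are on different grids")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")


def dmax_point(study: DoseStudy, mask: StructureMask) -> tuple[float, tuple]:
    """Maximum dose inside the mask and the arg-max voxel centre (mm).

    Ties resolve to the lowest (z, y, x) index so repeated runs and oracle
    scans agree bit for bit.
    """
    _require_mask(study.dose, mask)
    vals = study.dose.values
    member = mask.membership
    vmax = vals[member].max()
    cand = np.argwhere(member & (vals >= vmax))
    # lowest (z, y, x): sort candidate (x, y, z) indices by reversed tuple
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))
    idx = cand[order[0]]
    point = tuple(float(v) for v in study.grid.world_from_index(idx))
    return float(vmax), point


def cumulative_dvh(
    study: DoseStudy, mask: StructureMask, bin_width_pct: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of the mask with fixed-width dose bins (default 0.1%)."""
    _require_mask(study.dose, mask)
    doses = study.dose.values[mask.membership]
    vox_cc = study.grid.voxel_volume_cc
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_pct, bin_width_pct)
    # V(d) counts voxels with dose >= d
    counts = np.array([(doses >= d - 1e-12).sum() for d in edges], dtype=float)
    return DVHCurve(edges, counts * vox_cc)


def dose_at_volume(dvh: DVHCurve, v_cc: float) -> float:
    """Largest dose d with V(d) ≥ v_cc (linear interpolation between bins).

    ``dose_at_volume(dvh, 1.0)`` is D1cc, the minimum dose of the hottest
    cubic centimetre.
    """
    if not 0 < v_cc <= dvh.total_volume_cc + 1e-12:
        raise ValueError(
            f"v_cc={v_cc} outside (0, {dvh.total_volume_cc:.3f}] cc"
        )
    v = dvh.volume_cc
    d = dvh.dose_pct
    # v is non-increasing; find the last bin with V >= v_cc
    ok = v >= v_cc - 1e-12
    i = int(np.max(np.nonzero(ok)[0]))
    if i == len(v) - 1 or v[i] == v[i + 1]:
        return float(d[i])
    # interpolate within the drop from v[i] to v[i+1]
    frac = (v[i] - v_cc) / (v[i] - v[i + 1])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def geud(study: DoseStudy, mask: StructureMask, a: float = -20.0) -> float:
    """Generalized equivalent uniform dose: power mean of voxel doses.

    EUD = (mean over mask voxels of d_i^a)^(1/a) with tissue exponent ``a``
    (−20 for aggressive tumours, penalising cold spots).
    """
    _require_mask(study.dose, mask)
    if a == 0:
        raise ValueError("exponent a must be nonzero")
    doses = study.dose.values[mask.membership]
    if a < 0 and np.any(doses <= 0):
        raise ValueError("zero dose inside mask: power mean undefined for a < 0")
    # compute in log space for numerical safety at large |a|
    logs = a * np.log(doses)
    m = logs.max()
    return float(np.exp((m + np.log(np.mean(np.exp(logs - m)))) / a))


def delta_dmax(
    study_a: DoseStudy,
    mask_a: StructureMask,
    study_b: DoseStudy,
    mask_b: StructureMask,
) -> float:
    """Difference of the two *independent* structure maxima (not voxelwise)."""
    va, _ = dmax_point(study_a, mask_a)
    vb, _ = dmax_point(study_b, mask_b)
    return va - vb


def wor_sensitivity(
    plain: DoseStudy,
    overridden: DoseStudy,
    cbal_ptv: StructureMask,
    cbal: StructureMask,
    threshold_pct: float = 10.0,
) -> WORSensitivity:
    """Plan sensitivity to the water override of the air lumen."""
    if plain.wor or not overridden.wor:
        raise ValueError("expected plain.wor=False and overridden.wor=True")
    if (plain.ct_label, plain.plan_label) != (overridden.ct_label, overridden.plan_label):
        raise ValueError("water-override comparison requires the same plan and CT")
    if not plain.grid.same_geometry(overridden.grid):
        raise GridMismatchError("dose volumes are on different grids")
    dd = delta_dmax(overridden, cbal_ptv, plain, cbal_ptv)
    diff = overridden.dose.values - plain.dose.values
    member = cbal.membership & (diff > threshold_pct)
    v10 = StructureMask(cbal.grid, member, "V10_CBAL")
    return WORSensitivity(dd, v10, v10.volume_cc)


def gamma_pass_rate(
    reference: DoseStudy,
    evaluated: DoseStudy,
    region: StructureMask,
    dose_diff_pct: float = 2.0,
    dta_mm: float = 2.0,
    subsample_mm: float = 0.5,
) -> float:
    """Percent of region voxels passing the gamma 2%/2 mm criterion.

    Global normalization to the prescribed dose (100%); for each reference
    voxel the evaluated dose is probed trilinearly on a lattice of offsets
    at ``subsample_mm`` steps out to twice the distance-to-agreement, and
    γ² = min over offsets of (Δd / dose_diff)² + (‖Δr‖ / dta)².
    """
    _require_mask(reference.dose, region)
    if not reference.grid.same_geometry(evaluated.grid):
        raise GridMismatchError("gamma requires both doses on one grid")
    pts = region.centers_mm()
    ref_vals = reference.dose.values[region.membership]

    search = 2.0 * dta_mm
    steps = np.arange(-search, search + subsample_mm / 2, subsample_mm)
    ox, oy, oz = np.meshgrid(steps, steps, steps, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=-1)
    r2 = np.sum(offsets**2, axis=1)
    keep = r2 <= search**2 + 1e-9
    offsets, r2 = offsets[keep], r2[keep]
    order = np.argsort(r2)  # near offsets first so the early-exit bound bites
    offsets, r2 = offsets[order], r2[order]

    spacing = np.asarray(evaluated.grid.spacing)
    origin = np.asarray(evaluated.grid.origin)
    dims = np.asarray(evaluated.grid.dims)
    gamma2 = np.full(len(pts), np.inf)
    for off, rr in zip(offsets, r2):
        dist_term = rr / dta_mm**2
        active = gamma2 > dist_term  # this offset can still improve γ²
        if not active.any():
            continue
        idx = ((pts[active] + off) - origin) / spacing
        vals = ndimage.map_coordinates(
            evaluated.dose.values, idx.T, order=1, mode="nearest", prefilter=False
        )
        inside = np.all((idx >= 0) & (idx <= dims - 1), axis=1)
        dd2 = ((vals - ref_vals[active]) / dose_diff_pct) ** 2
        cand = np.where(inside, dd2 + dist_term, np.inf)
        gamma2[active] = np.minimum(gamma2[active], cand)
    return float(100.0 * np.mean(gamma2 <= 1.0 + 1e-9))


def compute_dose_metrics(
    study: DoseStudy,
    mask: StructureMask,
    v_cc: float = 1.0,
    eud_a: float | None = None,
) -> DoseMetrics:
    """Convenience bundle: Dmax (+ location), DVH, D1cc, optional gEUD."""
    vmax, point = dmax_point(study, mask)
    dvh = cumulative_dvh(study, mask)
    d1 = dose_at_volume(dvh, v_cc) if dvh.total_volume_cc >= v_cc else None
    eud_val = geud(study, mask, eud_a) if eud_a is not None else None
    return DoseMetrics(vmax, point, d1, eud_val, dvh)
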