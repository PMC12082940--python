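"""Measure anatomic change between a source and a subsequent CT.

A deformed copy of the phantom (rigid shift + smooth deformation, ground
truth known) stands in for the daily CT. The contour-based rigid alignment
of the bronchial tree recovers the shift; subtracting the clinical
registration gives the residual tree shift ‖CBTree‖. The deformation field
yields the shift at the wall hotspot, and the wall Dmax increase shows the
dose effect of the anatomy change.
"""

import numpy as np

from bronchodose import anatomy, dosimetry, motion, synthetic

ct, contours, _ = synthetic.make_phantom(
    synthetic.PhantomSpec(dims=(64, 64, 64), spacing_mm=2.0)
)
model = anatomy.derive_anatomy(ct, contours["CBT"], contours["CTV"])
plan = synthetic.make_plan(model, synthetic.ToyPlanSpec(boost_s_pct=12.0), 1)

shift = (2.0, -3.0, 4.0)
ct1, masks1, truth = synthetic.deform_anatomy(
    ct, {"CBT": contours["CBT"], "CTV": contours["CTV"]},
    rigid_shift_mm=shift, smooth_amp_mm=1.0, seed=11,
)
model1 = anatomy.derive_anatomy(ct1, masks1["CBT"], masks1["CTV"])

contour_reg = motion.rigid_align_masks(contours["CBT"], masks1["CBT"])
comps, norm = motion.residual_shift(contour_reg, motion.RigidTransform())
print(f"applied shift      : {shift}")
print(f"recovered ‖CBTree‖ : ({comps[0]:.2f}, {comps[1]:.2f}, {comps[2]:.2f})"
      f", norm {norm:.2f} mm")

dose0 = synthetic.calculate_dose(plan, ct)
dose1 = synthetic.calculate_dose(plan, ct1)
d0, _ = dosimetry.dmax_point(dose0, model["CBW"])
d1, p1 = dosimetry.dmax_point(dose1, model1["CBW"])
print(f"wall Dmax          : {d0:.2f}% on source -> {d1:.2f}% on subsequent CT")

shift_dmax = motion.dvf_shift_at_dmax(truth["dvf"], np.asarray(p1))
print(f"deformable shift at the hotspot (1-mm sphere mean): "
      f"{shift_dmax:.2f} mm")
print("\nthe alignment reads the applied motion back from contours alone, "
      "and the hotspot grows where air moved out of the boosted region")
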