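"""Score a plan's sensitivity to anatomy change by water override (WOR).

The toy plan boosts fluence into the lumen–PTV overlap by a tunable
amplitude s, emulating how an air-cavity-aware optimizer compensates
electron disequilibrium. Recomputing the dose with the lumen overridden to
water deposits that boost, so Dmax(WOR) − Dmax(plain) inside CBAL∩PTV
reads the boost back — the plan-sensitivity score. V10 is the lumen
subvolume whose dose rises by more than 10 % of the prescription.
"""

from bronchodose import anatomy, dosimetry, synthetic

ct, contours, _ = synthetic.make_phantom(
    synthetic.PhantomSpec(dims=(64, 64, 64), spacing_mm=3.0)
)
model = anatomy.derive_anatomy(ct, contours["CBT"], contours["CTV"])

for s in (2.0, 8.0, 15.0):
    plan = synthetic.make_plan(model, synthetic.ToyPlanSpec(boost_s_pct=s), 1)
    plain = synthetic.calculate_dose(plan, ct)
    wor = synthetic.calculate_dose(plan, ct, water_override=model["CBAL"])
    sens = dosimetry.wor_sensitivity(
        plain, wor, model["CBAL_PTV_m1"], model["CBAL"]
    )
    print(
        f"boost s = {s:4.1f}%  ->  WOR sensitivity = {sens.delta_dmax:5.2f}%"
        f"   V10 = {sens.v10_cc:5.2f} cc"
    )
print("\nthe sensitivity score recovers the boost amplitude; V10 appears "
      "once the boost exceeds the 10% threshold")
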