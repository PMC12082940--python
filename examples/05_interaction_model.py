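"""Fit the plan-sensitivity × density-change interaction model.

Fraction tables follow y = b0 + b_s·S + b_h·ΔHU + b_int·S·ΔHU + noise,
where S is the plan's water-override sensitivity (%) and ΔHU the density
change at the wall hotspot. The interaction carries the physics: density
change raises the hotspot only where the plan has boosted fluence into the
lumen. Five-fold cross-validation scores the fit out of sample.
"""

from bronchodose import stats as rstats
from bronchodose import synthetic

table, truth = synthetic.simulate_fraction_table(synthetic.SimTableSpec(seed=2))
print(f"simulated fraction table: {len(table)} rows "
      f"({table['patient_id'].nunique()} patients × 2 plan methods)")

fit = rstats.fit_interaction_model(table, "dmax_cbw_subsequent")
print(f"intercept b0   : {fit.b0:8.2f} %   (truth {truth['b0']})")
print(f"interaction    : {fit.b_int:.6f} ± {fit.se['b_int']:.6f} "
      f"%/(HU·%)  (truth {truth['b_int']})")
print(f"interaction p  : {fit.p_values['b_int']:.2e}")
print(f"main effects p : S {fit.p_values['b_s']:.2f}, "
      f"ΔHU {fit.p_values['b_h']:.2f}  (not significant alone)")

cv_r2, cv_rmse = rstats.crossvalidate_model(table, "dmax_cbw_subsequent",
                                            k=5, seed=2)
print(f"5-fold CV      : R² = {100 * cv_r2:.1f} %, RMSE = {cv_rmse:.2f} %")
print("\nonly the interaction term is significant — sensitivity moderates "
      "the effect of density change, neither factor acts alone")
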