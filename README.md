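# bronchodose

Robustness analysis of air-cavity-aware lung radiotherapy plans: does dose
homogeneity in the **central bronchial wall (CBW)** survive the anatomic
changes that occur between and within treatment fractions?

Dose engines that model lateral electron transport explicitly (linear
Boltzmann transport solvers) compensate electron disequilibrium by boosting
fluence into air cavities at the edge of the high-dose region. The plan is
then *sensitive* to anatomy: if the central bronchial air lumen (CBAL)
moves between the planning CT and the daily CT, the boosted fluence
deposits in tissue and a wall hotspot appears. This package implements, as
a tested and reusable pipeline, the full analysis of that effect for
online-adaptive radiotherapy of locally advanced lung cancer — structure
derivation, dosimetric and geometric per-fraction metrics, dose
accumulation, setup-margin estimation and the predictive interaction model
— exercised end to end on synthetic phantom anatomy, so no clinical data
are required. It is aimed at medical physicists and methodologists studying
plan robustness in thoracic adaptive radiotherapy.

## The model at the core

Three quantities drive the analysis, all in percent of the prescribed dose:

* **Plan sensitivity `S`** — the water-override (WOR) score: recompute the
  plan with the air lumen's density overridden to water; then
  `S = Dmax(CBAL∩PTV, +WOR) − Dmax(CBAL∩PTV, −WOR)`. It measures how much
  fluence the optimizer hid in the air cavity.
* **Density change `ΔHU`** — the Hounsfield-unit change at the wall-hotspot
  position between source and subsequent CT (clinically registered).
* **The interaction model** for the wall hotspot on the subsequent CT:

  `Dmax_CBW = b0 + b_s·S + b_h·ΔHU + b_int·(S·ΔHU) + ε`

  Neither factor acts alone: density change only matters where the plan is
  sensitive, so the multiplicative term `S·ΔHU` carries the effect. The
  model is scored by 5-fold cross-validation (out-of-fold R² and RMSE).

Around the model the pipeline computes Dmax (with location), D1cc, DVHs,
gEUD (power mean with exponent a = −20), gamma 2 %/2 mm pass rates, the
residual rigid tree shift ‖CBTree‖ after image guidance, deformable shift
at the hotspot, mean distance to agreement, hotspot-to-V10 Hausdorff
distance, mean-dose accumulation across fractions and van Herk setup
margins `M = 2.5Σ + 0.7σ`.

## Worked example

`examples/02_wor_sensitivity.py` builds a 64³ thorax phantom with a
bronchial tree, derives the structure system, freezes toy plans with
different fluence-boost amplitudes and scores them by water override:

```
boost s =  2.0%  ->  WOR sensitivity =  2.00%   V10 =  0.00 cc
boost s =  8.0%  ->  WOR sensitivity =  8.00%   V10 =  0.00 cc
boost s = 15.0%  ->  WOR sensitivity = 15.00%   V10 =  9.67 cc
```

The sensitivity score reads the hidden boost back exactly, and the V10
volume (lumen receiving > 10 % extra dose under override) appears once the
boost exceeds the threshold. `examples/05_interaction_model.py` fits the
interaction model on a simulated 182-row fraction table:

```
intercept b0   :   109.41 %   (truth 109.35)
interaction    : 0.000375 ± 0.000063 %/(HU·%)  (truth 0.000387)
interaction p  : 1.17e-08
main effects p : S 0.36, ΔHU 0.36  (not significant alone)
5-fold CV      : R² = 46.3 %, RMSE = 2.42 %
```

Only the interaction is significant — the sensitivity score moderates the
effect of density change. The other examples cover structure derivation,
motion metrics, margins/power and the full end-to-end study
(`examples/06_full_study.py`), whose adaptive-versus-scheduled regression
slope reads back the intra/inter motion ratio of 0.2.

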