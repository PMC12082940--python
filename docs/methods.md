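# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic study does and does not show about
clinical data.

## Coordinates, grids and masks

All geometry lives in the DICOM patient coordinate system (x right→left,
y anterior→posterior, z inferior→superior), distances in millimetres.
Voxel grids are axis-aligned; world coordinates are the exchange currency
between modules and 0-based indices never cross a module boundary. A voxel
belongs to a structure iff its *centre* satisfies the membership test, so
volumes are exact voxel counts × voxel volume and the inclusion–exclusion
identity holds exactly for boolean mask algebra. Masks are never resampled
implicitly; combining masks from different grids is an error. Resampling a
CT fills out-of-extent voxels with −1000 HU (air), dose with 0 % —
physically conservative defaults. RT Structure contours are rasterized per
axial slice by the voxel-centre test with XOR combination of polygons,
i.e. the even–odd rule; the inclusion rule at the contour boundary is our
choice, since treatment-planning systems do not standardise it.

## Structure system

From a CT plus two primary contours — the central bronchial tree (CBT:
trachea, main bronchi, intermediate bronchus, lobar bronchi to first
bifurcation) and the clinical CTV (contoured without the air lumen) — the
pipeline derives:

* **CBAL** — CBT voxels with HU strictly below −600 (strict "<" by
  definition of the lumen as content *below* the threshold);
* **CBW** — CBT expanded by an 8-mm Euclidean outer margin, minus CBAL.
  The expansion is not trimmed to a body contour (none exists on the
  phantom);
* **cCTV** — CTV within 20 mm of the CBT (the stereotactic "no-fly zone");
* **CTV-supplement** — lumen regions enclosed by the CTV once its boundary
  is closed across the lumen. Implemented as a reproducible geometric
  rule: per axial slice, lumen inside filled CTV holes plus lumen captured
  by a 2-D morphological closing with a disk wide enough to bridge the
  lumen (the "straight chord" a planner would draw). Clinically this is a
  manual contouring step; we commit to the geometric rule and validate it
  against a flood-fill oracle;
* **PTVs** by three methods: (1) supplement-unified CTV + 5 mm, (2)
  clinical CTV + 5 mm (may overlap the lumen), (3) as (2) but lumen voxels
  farther than 3 mm from the CTV surface are removed. The 3-mm limit is
  measured from the CTV surface into the lumen — one of two readings of
  "overlap limited to a margin of 3 mm"; the alternative (trimming the
  overlap to 3 mm depth from the PTV surface) differs only in degenerate
  geometries. The three methods give monotonically shrinking lumen–PTV
  overlap, the intended ordering of plan aggressiveness.

## Dosimetry

Dose is handled in percent of prescription throughout (absolute Gy in
metadata); every reported robustness quantity is on that scale. Dmax is a
voxel maximum without sub-voxel interpolation — the treatment-planning
convention, and it keeps brute-force oracles exact; ties resolve to the
lowest (z, y, x) index. The cumulative DVH uses 0.1 % bins; Dv (e.g. D1cc)
interpolates linearly between bins, which reproduces the sorted-voxel value
to better than the bin width. gEUD is the Niemierko power mean
`(mean dᵢᵃ)^(1/a)` with a = −20 for target tissue (strongly penalising
cold spots); zero-dose voxels with a < 0 are rejected rather than clamped.
DeltaDmax between two studies is the difference of *independent* structure
maxima, never a voxelwise difference. The gamma 2 %/2 mm evaluation uses
global normalization to the prescription, a search out to twice the
distance-to-agreement with 0.5-mm trilinear subsampling, and no low-dose
cut-off inside the evaluated structure (a declared choice; published
phantom work often cuts below 50 % of prescription). Gamma is asymmetric
in reference/evaluated by construction; we document but do not assert any
symmetry.

## Motion and accumulation

The contour-based rigid alignment of the bronchial tree drives the
residual-shift metric ‖CBTree‖ (contour alignment minus clinical
registration, per DICOM axis). It is implemented as Gauss–Newton descent
of the mean squared signed distance of the moving surface voxels to the
fixed mask's implicit surface, translation-initialized at the centroid
difference, deterministic, 50 iterations max, 10⁻⁴ mm convergence.
Point-to-implicit-surface matching was chosen over classic point-to-point
ICP because nearest-neighbour correspondence between two voxelized
surfaces is biased at coarse spacing (≈0.7 mm at 3 mm voxels); the
implicit-surface variant recovers synthetic rigid motions within
0.2 mm / 0.5° on the 2-mm phantom.

Deformation vector fields are inputs (clinically they come from hybrid
deformable registration, which is out of scope); each carries a mandatory
(from, to) direction flag and is applied as a pull-back with trilinear
interpolation. The deformable shift at the hotspot averages displacement
lengths over a 1-mm sphere. MDA is symmetric (mean of both directed mean
surface distances) — whether the clinical software reports the symmetric
or a directed value is unstated, so the symmetric choice is flagged. The
"Hausdorff distance" between the back-deformed hotspot and the V10 volume
is the *directed point-to-set* distance (0 inside, missing when V10 is
empty): the classical symmetric Hausdorff of a point versus a volume would
be dominated by the volume's far side and could not serve as a proximity
measure.

Accumulation averages per-fraction relative doses voxelwise, keeping the
accumulated distribution on the percent-of-prescription scale; hotspots
that wander between fractions therefore accumulate to less than the mean
of per-fraction maxima, which is the clinically relevant blurring effect.
Doses are mapped onto the planning CT along the inverted ground-truth
displacement field (fixed-point inversion, adequate for the smooth fields
used here).

## Statistics

* **Setup errors and margins.** Σ per axis is the SD over patients of
  per-patient mean shifts; σ is the RMS of within-patient SDs — the
  standard population decomposition, validated by reproducing all six
  published margins from the published Σ/σ. The margin recipe is fixed at
  M = 2.5Σ + 0.7σ (population 90 % coverage).
* **Interaction model.** OLS on {1, S, ΔHU, S·ΔHU} with coefficient SEs
  and two-sided t-tests; rank-deficient designs are rejected. K-fold CV
  assigns rows uniformly at random (seeded), refits from scratch per fold
  and reports R² = 1 − SSE/SST over pooled held-out predictions (the
  squared-correlation alternative was rejected as it hides calibration
  error) plus the out-of-fold RMSE.
* **Stratified Wilcoxon.** Van Elteren combination with weights
  1/(n_s + 1), tie-corrected variance, normal approximation. The
  continuity correction is half the smallest lattice step of the *weighted*
  statistic; the conventional 0.5 (appropriate for an unweighted rank sum)
  makes the test badly conservative at small strata (empirical size 0.016
  instead of 0.05). With the corrected step the empirical size is ≈0.056
  at nominal 0.05.
* **Signed rank / Kruskal–Wallis** use exact (n ≤ 25, no ties) or
  tie-corrected asymptotic distributions via scipy. Exact p-values are
  discrete, hence stepwise super-uniform under the null; tests check
  validity and decile-level uniformity rather than a strict KS match.
* **Variable clustering** is agglomerative with average linkage on
  1 − |r|. This deviates from divisive PCA-based variance clustering
  (SAS VARCLUS); what the analysis needs — recovery of correlated blocks —
  is invariant to that choice.
* **Power.** The cohort power for detecting R² = 0.5 uses the noncentral-t
  distribution of the correlation t statistic with df = n − 2 and
  noncentrality √n·ρ/√(1 − ρ²) — the fixed-regressor (point-biserial)
  model used by standard power software, which reproduces the design value
  0.88 for n = 10 at one-tailed α = 0.05. Note this is *not* the power of
  the random-regressor bivariate-normal test (≈0.80 by simulation); the
  Monte Carlo cross-check therefore conditions on standardized regressors.

## The synthetic generator

The generator defines the study conditions; every generator returns its
ground truth for oracle testing and is bit-reproducible per seed.

* **Phantom** (default 2-mm isotropic, 128³; the study runs at 3 mm, 64³):
  a branching capsule tree — trachea (r = 8 mm) bifurcating into main
  bronchi (5.5 mm) and lobar stubs (4 mm), wall thickness 2.5 mm — in lung
  background (−780 HU), lumen −1000 HU, wall 0 HU, and a tumour (+30 HU,
  radius ≈ 24 mm) wrapping partway around the trachea so that every
  structure-derivation rule is exercised non-trivially.
* **Toy dose engine.** Not a transport solver. The plan freezes two fields
  in room coordinates on its source anatomy: a base dose (100 % inside the
  PTV, Gaussian penumbra σ = 5 mm) and a fluence boost
  `B(x) = s·exp(−d(x, CBAL∩PTV)²/2σ_b²)` with σ_b = 2 mm. Evaluated on any
  CT, the deposited dose is `base + B·(1 − a)` where `a` is the local air
  fraction from HU (1 at −1000, 0 at ≥ 0 HU); a water override sets a = 0
  inside the lumen. This reproduces the two behaviours the analysis
  probes: the override reads back s exactly, and anatomy motion that
  replaces air by tissue in the boosted region raises the wall hotspot
  approximately linearly in s × ΔHU. It does not model scatter, beam
  geometry, or dose build-up, so absolute hotspot magnitudes are
  illustrative only.
* **Deformed anatomies** apply a rigid shift plus smooth Gaussian-filtered
  noise (15-mm correlation scale). Masks are warped through their signed
  distance so the deformed boundary lands at sub-voxel accuracy.
  Intra-fractional motion reuses the same displacement realization scaled
  by 0.2 — breathing/settling acts along the same anatomical modes — which
  is what makes the adaptive-versus-scheduled slope identifiable.
* **Fraction tables** draw S log-uniformly over 1.7–22.1 % (per
  patient × plan method, a plan property) and ΔHU per fraction from a
  bimodal mixture (small jitter N(0, 150 HU), or an air/tissue swap
  ±N(900, 80 HU) with probability 0.6). Responses follow the interaction
  model with intercept 109.35 %, interaction 0.000387 %/(HU·%), patient
  random effect SD 1.0 % and residual SD 2.45 %, calibrated so the
  out-of-fold RMSE is ≈2.65 % and the model explains ≈half the variance —
  the clinically observed fit regime.

## Study wiring and problem sizes

Inter-fractional scenario: planning CT → daily CT with scheduled plans
(methods 1 and 2, both computed per fraction). Intra-fractional: daily CT
→ post-adaptation CT with the adaptive plan re-optimized on the daily
anatomy. The default synthetic study runs 10 patients, 91 fractions, 64³
grids at 3 mm — sizes chosen so a full study completes in minutes on one
CPU while every metric remains non-trivial. Incomplete fractions (e.g.
missing DVF) are flagged, never silently dropped.

## Known limitations

* At the study's 3-mm grid, binary masks quantize contour positions to
  about half a voxel, so the ~0.2–0.7 mm intra-fractional rigid shifts are
  below the contour resolution: recovered intra-fractional margins are
  near zero and should be read as "below resolution", not as estimates.
  The DVF-based shift-at-hotspot metric is continuous and unaffected, and
  the margin formula itself is validated on published error
  decompositions.
* The toy engine concentrates the boost at the wall adjacent to the lumen,
  so the hotspot-to-V10 Hausdorff distance has little dynamic range and
  its correlation with Dmax is weak on the synthetic study (clinically it
  is clearly negative). The metric itself is oracle-tested.
* Passing the synthetic suite shows the *machinery* is correct and that
  the published regime (margins, power, model recovery, robustness ratio)
  is reproduced under the stated conditions; it does not certify clinical
  dose accuracy, which requires a real dose engine and real anatomy.
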