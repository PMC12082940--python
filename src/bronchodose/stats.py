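"""Statistical layer: van Herk margins, the interaction model with k-fold
cross-validation, stratified nonparametric tests, variable clustering,
shift-sensitivity polynomial fits and the correlation power analysis.

The central model regresses the wall hotspot dose (or its inter-study
increase) on the plan's water-override sensitivity S (%), the density
change ΔHU at the hotspot, and their product::

    y = b0 + b_s·S + b_h·ΔHU + b_int·(S·ΔHU) + ε

The interaction term carries the physics: density change only matters where
the plan has boosted fluence into the air lumen, so S moderates the effect
of ΔHU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
import statsmodels.api as sm

__all__ = [
    "SensitivityModel",
    "MarginReport",
    "error_decomposition",
    "van_herk_margin",
    "margin_report",
    "fit_interaction_model",
    "crossvalidate_model",
    "stratified_wilcoxon",
    "rank_tests",
    "cluster_variables",
    "shift_sensitivity_curve",
    "power_r2",
]

AXES = ("x", "y", "z")


@dataclass
class SensitivityModel:
    """Fitted interaction-model coefficients with cross-validation scores."""

    b0: float
    b_s: float
    b_h: float
    b_int: float
    se: dict[str, float]
    p_values: dict[str, float]
    cv_r2: float | None = None
    cv_rmse: float | None = None
    n: int = 0

    @property
    def coefficients(self) -> dict[str, float]:
        return {"b0": self.b0, "b_s": self.b_s, "b_h": self.b_h,
                "b_int": self.b_int}


@dataclass
class MarginReport:
    """Per-axis systematic/random setup errors and van Herk margins (mm)."""

    scope: str  # "inter" or "intra"
    systematic_mm: dict[str, float]
    random_mm: dict[str, float]
    margin_mm: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": list(AXES),
                "systematic_mm": [self.systematic_mm[a] for a in AXES],
                "random_mm": [self.random_mm[a] for a in AXES],
                "margin_mm": [self.margin_mm[a] for a in AXES],
                "scope": self.scope,
            }
        )


def error_decomposition(
    shifts: pd.DataFrame,
    patient_col: str = "patient_id",
    axis_cols: tuple[str, str, str] = ("dx", "dy", "dz"),
) -> tuple[dict[str, float], dict[str, float]]:
    """Population setup-error decomposition per axis.

    Σ (systematic) is the standard deviation over patients of the
    per-patient mean shifts; σ (random) is the root mean square over
    patients of the within-patient standard deviations.
    """
    groups = shifts.groupby(patient_col)
    if groups.ngroups < 2:
        raise ValueError("systematic error undefined with a single patient")
    if (groups.size() < 2).any():
        raise ValueError("each patient needs at least two fractions")
    systematic, random = {}, {}
    for axis, col in zip(AXES, axis_cols):
        means = groups[col].mean()
        sds = groups[col].std(ddof=1)
        systematic[axis] = float(means.std(ddof=1))
        random[axis] = float(np.sqrt(np.mean(sds**2)))
    return systematic, random


def van_herk_margin(systematic_mm: float, random_mm: float) -> float:
    """Population PTV margin M = 2.5Σ + 0.7σ (90% coverage recipe)."""
    if systematic_mm < 0 or random_mm < 0:
        raise ValueError("setup errors must be non-negative")
    return 2.5 * systematic_mm + 0.7 * random_mm


def margin_report(
    systematic: dict[str, float], random: dict[str, float], scope: str
) -> MarginReport:
    margins = {a: van_herk_margin(systematic[a], random[a]) for a in AXES}
    return MarginReport(scope, dict(systematic), dict(random), margins)


def _design(records: pd.DataFrame, s_col: str, h_col: str) -> np.ndarray:
    s = records[s_col].to_numpy(dtype=float)
    h = records[h_col].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(s), s, h, s * h])


def fit_interaction_model(
    records: pd.DataFrame,
    response: str,
    s_col: str = "wor_sensitivity_s",
    h_col: str = "delta_hu_at_dmax",
) -> SensitivityModel:
    """OLS of the response on {1, S, ΔHU, S·ΔHU} with SEs and t-test p-values."""
    if len(records) < 10:
        raise ValueError("need at least 10 rows to fit the interaction model")
    X = _design(records, s_col, h_col)
    y = records[response].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite predictors or response")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: a predictor has no variance")
    fit = sm.OLS(y, X).fit()
    names = ("b0", "b_s", "b_h", "b_int")
    return SensitivityModel(
        *(float(c) for c in fit.params),
        se={k: float(v) for k, v in zip(names, fit.bse)},
        p_values={k: float(v) for k, v in zip(names, fit.pvalues)},
        n=len(records),
    )


def crossvalidate_model(
    records: pd.DataFrame,
    response: str,
    k: int = 5,
    seed: int = 0,
    s_col: str = "wor_sensitivity_s",
    h_col: str = "delta_hu_at_dmax",
) -> tuple[float, float]:
    """k-fold cross-validation of the interaction model.

    Rows are split uniformly at random into k disjoint folds; each fold is
    scored by a model refit from scratch on the other k−1. Returns
    (cv_r2, cv_rmse) over the pooled held-out predictions, with
    cv_r2 = 1 − SSE/SST.
    """
    n = len(records)
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k rows")
    X = _design(records, s_col, h_col)
    y = records[response].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(n) % k)
    if np.bincount(fold, minlength=k).min() < X.shape[1] + 1:
        raise ValueError("a fold has fewer rows than model parameters + 1")
    pred = np.empty(n)
    for f in range(k):
        test = fold == f
        beta, *_ = np.linalg.lstsq(X[~test], y[~test], rcond=None)
        pred[test] = X[test] @ beta
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst, float(np.sqrt(sse / n))


def stratified_wilcoxon(
    values: np.ndarray,
    conditions: np.ndarray,
    strata: np.ndarray,
) -> float:
    """Two-sided stratified (van Elteren) Wilcoxon rank-sum test.

    Within each stratum (patient) the two conditions are compared by the
    Wilcoxon rank-sum statistic; stratum statistics are combined with van
    Elteren weights 1/(n_s + 1) and referred to a normal approximation with
    tie-corrected variance. The continuity correction is half the smallest
    lattice step of the *weighted* statistic (the raw 0.5 of the unweighted
    rank sum would be far too coarse and makes the test conservative).
    """
    values = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    strata = np.asarray(strata)
    levels = np.unique(conditions)
    if len(levels) != 2:
        raise ValueError("stratified Wilcoxon compares exactly two conditions")
    T = 0.0
    ET = 0.0
    VT = 0.0
    used = 0
    min_step = np.inf
    for s in np.unique(strata):
        in_s = strata == s
        g1 = values[in_s & (conditions == levels[0])]
        g2 = values[in_s & (conditions == levels[1])]
        n1, n2 = len(g1), len(g2)
        if n1 == 0 or n2 == 0:
            warnings.warn(f"stratum {s!r} lacks one condition; dropped",
                          stacklevel=2)
            continue
        used += 1
        ns = n1 + n2
        ranks = sps.rankdata(np.concatenate([g1, g2]))
        w = 1.0 / (ns + 1)
        W = ranks[:n1].sum()
        # tie correction for the rank-sum variance
        _, counts = np.unique(values[in_s], return_counts=True)
        tie = np.sum(counts**3 - counts) / (ns * (ns - 1)) if ns > 1 else 0.0
        var_w = n1 * n2 / 12.0 * (ns + 1 - tie)
        T += w * W
        ET += w * n1 * (ns + 1) / 2.0
        VT += w**2 * var_w
        min_step = min(min_step, w)
    if used < 2:
        raise ValueError("need at least two usable strata")
    if VT <= 0:
        return 1.0
    diff = T - ET
    cc = 0.5 * min_step if diff != 0 else 0.0
    z = (abs(diff) - cc) / np.sqrt(VT)
    return float(2.0 * sps.norm.sf(max(z, 0.0)))


def rank_tests(
    values,
    groups=None,
    kind: str = "kruskal_wallis",
) -> float:
    """Kruskal–Wallis (``values`` per group) or Wilcoxon signed-rank test.

    For the signed-rank test ``values`` are paired differences; the exact
    null distribution is used up to n = 25, the tie-corrected normal
    approximation above.
    """
    if kind == "kruskal_wallis":
        if groups is None:
            raise ValueError("Kruskal-Wallis needs group labels")
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        samples = [values[groups == g] for g in np.unique(groups)]
        return float(sps.kruskal(*samples).pvalue)
    if kind == "signed_rank":
        diffs = np.asarray(values, dtype=float)
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            warnings.warn("all differences are zero; p = 1", stacklevel=2)
            return 1.0
        method = "exact" if len(nz) <= 25 and not _has_tied_abs(nz) else "approx"
        return float(sps.wilcoxon(diffs, zero_method="wilcox",
                                  method=method).pvalue)
    raise ValueError(f"unknown rank test {kind!r}")


def _has_tied_abs(diffs: np.ndarray) -> bool:
    a = np.abs(diffs)
    return len(np.unique(a)) < len(a)


def cluster_variables(
    correlation: pd.DataFrame | np.ndarray, n_clusters: int | None = None
):
    """Hierarchical clustering of variables on the distance 1 − |r|.

    Average-linkage agglomeration; returns the scipy linkage matrix and,
    when ``n_clusters`` is given, flat cluster labels per variable.
    """
    if isinstance(correlation, pd.DataFrame):
        names = list(correlation.columns)
        corr = correlation.to_numpy(dtype=float)
    else:
        corr = np.asarray(correlation, dtype=float)
        names = [f"v{i}" for i in range(corr.shape[0])]
    if corr.shape[0] != corr.shape[1] or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if n_clusters is None:
        return Z, names
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, dict(zip(names, labels.tolist()))


def shift_sensitivity_curve(
    shift_mm,
    dmax_values,
    degree: int = 6,
    conf_level: float = 0.95,
):
    """Polynomial fit of hotspot dose against isocenter shift with CI band.

    Least squares of ``dmax_values`` on powers of ``shift_mm`` up to
    ``degree`` (default 6); returns ``(coefficients ascending, fitted
    values, (lower, upper))`` where the band is the pointwise confidence
    interval for the mean prediction at the input shifts.
    """
    x = np.asarray(shift_mm, dtype=float)
    y = np.asarray(dmax_values, dtype=float)
    if len(x) < degree + 2:
        raise ValueError("need at least degree + 2 points")
    X = np.vander(x, degree + 1, increasing=True)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=1 - conf_level)
    return (
        np.asarray(fit.params, dtype=float),
        pred["mean"].to_numpy(),
        (pred["mean_ci_lower"].to_numpy(), pred["mean_ci_upper"].to_numpy()),
    )


def power_r2(r2: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Power to detect a Pearson correlation of magnitude √r2 at size n.

    Uses the noncentral-t distribution of the correlation t-statistic with
    df = n − 2 and noncentrality √n·ρ/√(1 − ρ²).
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    rho = np.sqrt(r2)
    df = n - 2
    nc = np.sqrt(n) * rho / np.sqrt(1 - rho**2)
    crit = sps.t.ppf(1 - alpha / tails, df)
    power = sps.nct.sf(crit, df, nc)
    if tails == 2:
        power += sps.nct.cdf(-crit, df, nc)
    return float(power)
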