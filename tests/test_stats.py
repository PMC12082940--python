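import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bronchodose import stats as rstats
from bronchodose import synthetic as synth


class TestErrorDecomposition:
    @staticmethod
    def _table(shifts_by_patient):
        rows = []
        for pid, shifts in shifts_by_patient.items():
            for s in shifts:
                rows.append({"patient_id": pid, "dx": s[0], "dy": s[1],
                             "dz": s[2]})
        return pd.DataFrame(rows)

    def test_all_zero_shifts(self):
        tab = self._table({p: [(0, 0, 0)] * 4 for p in "abc"})
        sig, rnd = rstats.error_decomposition(tab)
        assert all(v == 0 for v in sig.values())
        assert all(v == 0 for v in rnd.values())

    def test_constant_per_patient_is_pure_systematic(self):
        consts = {"a": (1, 0, 2), "b": (-1, 0, 0), "c": (3, 0, -2)}
        tab = self._table({p: [c] * 5 for p, c in consts.items()})
        sig, rnd = rstats.error_decomposition(tab)
        assert all(v == pytest.approx(0, abs=1e-12) for v in rnd.values())
        assert sig["x"] == pytest.approx(np.std([1, -1, 3], ddof=1))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(7)
        sig_true, rnd_true = 1.5, 1.0
        rows = []
        for p in range(10):
            mu = rng.normal(0, sig_true, 3)
            for f in range(10):
                s = mu + rng.normal(0, rnd_true, 3)
                rows.append({"patient_id": p, "dx": s[0], "dy": s[1],
                             "dz": s[2]})
        sig, rnd = rstats.error_decomposition(pd.DataFrame(rows))
        for axis in "xyz":
            assert abs(sig[axis] - sig_true) / sig_true < 0.30
            assert abs(rnd[axis] - rnd_true) / rnd_true < 0.30

    def test_single_patient_rejected(self):
        tab = self._table({"a": [(0, 0, 0)] * 4})
        with pytest.raises(ValueError):
            rstats.error_decomposition(tab)


class TestVanHerk:
    def test_zero_errors_zero_margin(self):
        assert rstats.van_herk_margin(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rstats.van_herk_margin(-1.0, 0.5)

    @pytest.mark.parametrize(
        "sigma,rand,expected",
        [(1.32, 0.88, 3.9), (1.59, 1.15, 4.8), (2.23, 0.93, 6.2),
         (0.18, 0.68, 0.9), (0.91, 1.35, 3.2), (0.79, 1.11, 2.8)],
    )
    def test_reported_setup_margins(self, sigma, rand, expected):
        assert round(rstats.van_herk_margin(sigma, rand), 1) == expected


class TestInteractionModel:
    def test_noise_free_recovery_to_six_digits(self):
        rng = np.random.default_rng(0)
        n = 60
        s = rng.uniform(1.7, 22.1, n)
        h = rng.uniform(-1000, 1000, n)
        y = 109.35 + 0.000387 * s * h
        tab = pd.DataFrame(
            {"wor_sensitivity_s": s, "delta_hu_at_dmax": h, "resp": y}
        )
        m = rstats.fit_interaction_model(tab, "resp")
        assert m.b0 == pytest.approx(109.35, rel=1e-6)
        assert m.b_int == pytest.approx(0.000387, rel=1e-6)
        assert m.b_s == pytest.approx(0.0, abs=1e-9)
        assert m.b_h == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_predictor_rejected(self):
        tab = pd.DataFrame(
            {
                "wor_sensitivity_s": np.ones(20),
                "delta_hu_at_dmax": np.ones(20),
                "resp": np.random.default_rng(0).normal(size=20),
            }
        )
        with pytest.raises(ValueError):
            rstats.fit_interaction_model(tab, "resp")

    def test_interaction_coefficient_coverage(self):
        # with noise, the ±2 SE interval should cover the truth ~95% of runs
        hits = 0
        reps = 200
        for i in range(reps):
            tab, truth = synth.simulate_fraction_table(
                synth.SimTableSpec(seed=10_000 + i)
            )
            m = rstats.fit_interaction_model(tab, "dmax_cbw_subsequent")
            if abs(m.b_int - truth["b_int"]) <= 2 * m.se["b_int"]:
                hits += 1
        assert hits / reps >= 0.93


class TestCrossValidation:
    def test_perfect_linear_data(self):
        rng = np.random.default_rng(1)
        n = 100
        s = rng.uniform(1, 20, n)
        h = rng.uniform(-500, 500, n)
        tab = pd.DataFrame(
            {
                "wor_sensitivity_s": s,
                "delta_hu_at_dmax": h,
                "resp": 100 + 0.1 * s + 0.002 * h + 0.0005 * s * h,
            }
        )
        cv_r2, cv_rmse = rstats.crossvalidate_model(tab, "resp", seed=3)
        assert cv_r2 == pytest.approx(1.0, abs=1e-9)
        assert cv_rmse == pytest.approx(0.0, abs=1e-6)

    def test_pure_noise_has_nonpositive_skill(self):
        rng = np.random.default_rng(2)
        scores = []
        for i in range(100):
            tab = pd.DataFrame(
                {
                    "wor_sensitivity_s": rng.uniform(1, 20, 60),
                    "delta_hu_at_dmax": rng.uniform(-500, 500, 60),
                    "resp": rng.normal(size=60),
                }
            )
            scores.append(rstats.crossvalidate_model(tab, "resp", seed=i)[0])
        assert np.mean(scores) <= 0.0

    def test_deterministic_given_seed(self):
        tab, _ = synth.simulate_fraction_table(synth.SimTableSpec(seed=5))
        a = rstats.crossvalidate_model(tab, "dmax_cbw_subsequent", seed=9)
        b = rstats.crossvalidate_model(tab, "dmax_cbw_subsequent", seed=9)
        assert a == b


class TestStratifiedWilcoxon:
    @staticmethod
    def _build(rng, n_strata=10, n_per=9, shift=0.0):
        values, conds, strata = [], [], []
        for s in range(n_strata):
            base = rng.normal(100, 5, n_per)
            values.extend(base)
            conds.extend(["a"] * n_per)
            strata.extend([s] * n_per)
            values.extend(rng.normal(100 + shift, 5, n_per))
            conds.extend(["b"] * n_per)
            strata.extend([s] * n_per)
        return np.array(values), np.array(conds), np.array(strata)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        v, c, s = self._build(rng, shift=0.0)
        assert rstats.stratified_wilcoxon(v, c, s) > 0.05

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        v, c, s = self._build(rng, shift=20.0)
        assert rstats.stratified_wilcoxon(v, c, s) < 1e-4

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            v, c, s = self._build(rng, n_strata=6, n_per=6, shift=0.0)
            if rstats.stratified_wilcoxon(v, c, s) < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestRankTests:
    def test_exact_signed_rank_matches_enumeration(self):
        # {1, 2, 3, -4}: W+ = 6; exact two-sided p from all 2^4 sign flips
        diffs = np.array([1.0, 2.0, 3.0, -4.0])
        got = rstats.rank_tests(diffs, kind="signed_rank")
        ranks = sps.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        stats = []
        for signs in range(16):
            flip = np.array([(signs >> k) & 1 for k in range(4)], dtype=bool)
            stats.append(ranks[~flip].sum())
        stats = np.array(stats)
        n = len(stats)
        mu = ranks.sum() / 2
        p_exact = np.mean(np.abs(stats - mu) >= np.abs(w_obs - mu) - 1e-12)
        assert got == pytest.approx(p_exact)

    def test_identical_groups_kruskal_not_significant(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=60)
        g = np.repeat(["a", "b", "c"], 20)
        assert rstats.rank_tests(v, groups=g, kind="kruskal_wallis") > 0.05

    def test_null_p_values_uniform_and_valid(self):
        # exact-test p-values are discrete, hence stepwise super-uniform:
        # check validity at 0.05 and closeness to uniform at the deciles
        rng = np.random.default_rng(4)
        ps = np.array(
            [
                rstats.rank_tests(rng.normal(size=20), kind="signed_rank")
                for _ in range(2000)
            ]
        )
        assert 0.035 <= np.mean(ps <= 0.05) <= 0.065
        for alpha in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert abs(np.mean(ps <= alpha) - alpha) <= 0.04

    def test_all_zero_diffs_p_one(self):
        with pytest.warns(UserWarning):
            assert rstats.rank_tests(np.zeros(10), kind="signed_rank") == 1.0


class TestClusterVariables:
    @staticmethod
    def _block_corr():
        c = np.full((6, 6), 0.1)
        c[:3, :3] = 0.9
        c[3:, 3:] = 0.9
        np.fill_diagonal(c, 1.0)
        return c

    def test_block_structure_recovered(self):
        Z, labels = rstats.cluster_variables(
            pd.DataFrame(self._block_corr(),
                         columns=list("abcdef"), index=list("abcdef")),
            n_clusters=2,
        )
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        assert labels["a"] != labels["d"]

    def test_identity_matrix_all_singletons(self):
        Z, labels = rstats.cluster_variables(np.eye(5), n_clusters=5)
        assert len(set(labels.values())) == 5

    def test_permutation_invariance(self):
        corr = self._block_corr()
        perm = [3, 0, 4, 1, 5, 2]
        permuted = corr[np.ix_(perm, perm)]
        _, lab1 = rstats.cluster_variables(corr, n_clusters=2)
        _, lab2 = rstats.cluster_variables(permuted, n_clusters=2)
        names1 = ["v%d" % i for i in range(6)]
        group1 = {n: lab1[n] for n in names1}
        # variable originally at position perm[i] is at position i now
        same1 = group1["v0"] == group1["v1"]
        same2 = lab2["v1"] == lab2["v3"]  # v1,v3 in permuted = orig 0,1
        assert same1 == same2

    def test_asymmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            rstats.cluster_variables(bad)


class TestShiftSensitivityCurve:
    def test_exact_degree_six_recovery(self):
        rng = np.random.default_rng(5)
        coeffs_true = rng.normal(size=7)
        x = np.linspace(-15, 15, 20)
        y = np.polyval(coeffs_true[::-1], x)
        coeffs, fitted, band = rstats.shift_sensitivity_curve(x, y)
        assert np.allclose(coeffs, coeffs_true, rtol=1e-6, atol=1e-8)

    def test_quadratic_term_detected_under_noise(self):
        rng = np.random.default_rng(6)
        import statsmodels.api as sm

        hits = 0
        for _ in range(50):
            x = np.linspace(-15, 15, 40)
            y = 100 + 0.05 * x**2 + rng.normal(0, 2.0, len(x))
            X = np.vander(x, 3, increasing=True)
            fit = sm.OLS(y, X).fit()
            if fit.pvalues[2] < 0.05:
                hits += 1
        assert hits >= 45  # quadratic detected in >= 90% at this SNR

    def test_unshifted_value_inside_band_at_zero(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([[0.0], np.linspace(-15, 15, 19)])
        y0 = 104.0
        y = y0 + 0.04 * x**2 + rng.normal(0, 0.5, len(x))
        _, fitted, (lo, hi) = rstats.shift_sensitivity_curve(x, y)
        assert lo[0] - 1.0 <= y0 <= hi[0] + 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rstats.shift_sensitivity_curve(np.arange(5), np.arange(5))


class TestPower:
    def test_reported_design_power(self):
        # 10 patients suffice for R² = 0.5 at one-tailed alpha 0.05
        assert rstats.power_r2(0.5, 10, 0.05, tails=1) == pytest.approx(
            0.88, abs=0.02
        )

    def test_power_approaches_one(self):
        assert rstats.power_r2(0.95, 40) > 0.999

    def test_matches_fixed_regressor_monte_carlo(self):
        # simulate the fixed-regressor (point-biserial style) t-test the
        # noncentral-t formula describes
        rng = np.random.default_rng(8)
        r2, n, alpha = 0.5, 10, 0.05
        rho = np.sqrt(r2)
        reps = 100_000
        x = rng.standard_normal(n)
        x = (x - x.mean()) / np.sqrt(np.mean((x - x.mean()) ** 2))
        eps = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * eps
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        r = (yc @ xc) / np.sqrt((xc @ xc) * (yc**2).sum(axis=1))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        crit = sps.t.ppf(1 - alpha, n - 2)
        mc_power = float(np.mean(t > crit))
        assert rstats.power_r2(r2, n, alpha) == pytest.approx(mc_power, abs=0.01)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            rstats.power_r2(1.5, 10)
        with pytest.raises(ValueError):
            rstats.power_r2(0.5, 3)
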