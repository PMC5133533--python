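"""Per-window association tests: filtering, statistics, p-values."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

from regskat import assoc
from regskat.nullmodel import fit_null


def _unrelated_fit(rng, n, p=2):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    y = X @ np.ones(p + 1) + rng.standard_normal(n)
    return fit_null(y, X, np.eye(n)), y, X


class TestFilterRare:
    def test_common_allele_folded_then_removed(self, rng):
        g = rng.binomial(2, 0.60, size=(200, 1)).astype(float)
        assert assoc.filter_rare(g) is None  # folded MAF 0.40 >= 0.05

    def test_monomorphic_column_removed(self):
        g = np.zeros((50, 2))
        g[:, 1] = rng_col = np.r_[np.ones(2), np.zeros(48)]
        win = assoc.filter_rare(g)
        assert win.m == 1 and win.kept.tolist() == [1]

    def test_doubleton_in_789_samples_retained(self):
        g = np.zeros((789, 1))
        g[[10, 500], 0] = 1.0
        win = assoc.filter_rare(g)
        assert win is not None
        assert win.mafs[0] == pytest.approx(2 / (2 * 789))

    def test_threshold_is_strict(self):
        n = 100
        g = np.zeros((n, 1))
        g[:10] = 1.0  # 10 carriers of 200 alleles: exactly MAF 0.05
        assert np.nansum(g) / (2 * n) == 0.05
        assert assoc.filter_rare(g) is None

    def test_missing_imputed_to_twice_maf(self):
        g = np.array([[1.0], [0.0], [0.0], [0.0], [np.nan]] + [[0.0]] * 45)
        win = assoc.filter_rare(g)
        maf = 1 / (2 * 49)
        assert win.mafs[0] == pytest.approx(maf)
        assert win.G[4, 0] == pytest.approx(2 * maf)

    def test_fold_happens_before_imputation(self):
        g = np.full((60, 1), 2.0)
        g[:5] = 1.0
        g[5] = np.nan
        win = assoc.filter_rare(g)
        # folded: five heterozygotes carry the (now) minor allele
        assert win.mafs[0] == pytest.approx(5 / (2 * 59))
        assert win.G[5, 0] == pytest.approx(2 * win.mafs[0])


class TestStatistics:
    def test_zero_residuals_give_zero_statistic(self, rng):
        win = assoc.GenotypeWindow(rng.integers(0, 2, (30, 4)).astype(float),
                                   np.full(4, 0.02), np.arange(4))
        assert assoc.skat_statistic(win, np.ones(4), np.zeros(30)) == 0.0

    def test_single_variant_statistic_is_squared_score(self, rng):
        g = rng.integers(0, 2, (30, 1)).astype(float)
        win = assoc.GenotypeWindow(g, np.array([0.02]), np.array([0]))
        resid = rng.standard_normal(30)
        expected = float(g[:, 0] @ resid) ** 2
        assert assoc.skat_statistic(win, np.ones(1), resid) == \
            pytest.approx(expected)

    def test_category6_windows_make_reg_equal_unweighted(self, rng):
        n = 150
        fit, _, _ = _unrelated_fit(rng, n)
        g = rng.binomial(1, 0.03, (n, 5)).astype(float)
        win = assoc.filter_rare(g)
        cats = np.full(win.m, 6)
        results = {r.method: r for r in assoc.run_window(win, fit, cats, "w")}
        assert results["regSKAT"].statistic == \
            pytest.approx(results["uwSKAT"].statistic)
        assert results["regSKAT"].p_value == \
            pytest.approx(results["uwSKAT"].p_value, rel=1e-9)
        assert results["regT5"].p_value == \
            pytest.approx(results["T5"].p_value, rel=1e-9)

    def test_single_variant_all_six_methods_agree(self, rng):
        n = 200
        fit, _, _ = _unrelated_fit(rng, n)
        g = rng.binomial(1, 0.02, (n, 1)).astype(float)
        win = assoc.filter_rare(g)
        results = assoc.run_window(win, fit, [2], "w")
        ps = [r.p_value for r in results]
        assert len(results) == 6
        assert ps == pytest.approx([ps[0]] * 6, rel=1e-9)

    def test_single_variant_p_matches_single_variant_regression(self, rng):
        n = 300
        fit, y, X = _unrelated_fit(rng, n)
        g = rng.binomial(1, 0.04, (n, 1)).astype(float)
        win = assoc.filter_rare(g)
        wsq = np.ones(1)
        stat = assoc.skat_statistic(win, wsq, fit.resid_proj)
        p, _ = assoc.skat_pvalue(stat, win, wsq, fit)
        # independent oracle: t-test of the variant in OLS (exact match),
        # which the two-sided normal score test approaches asymptotically
        import statsmodels.api as sm
        ols = sm.OLS(y, np.column_stack([X, win.G])).fit()
        assert p == pytest.approx(ols.pvalues[-1], rel=1e-6)
        GPy, GPG = fit.quadratics(win.G)
        z = GPy[0] / np.sqrt(GPG[0, 0])
        assert p == pytest.approx(2 * norm.sf(abs(z)), abs=2e-3)

    def test_weight_scale_invariance(self, rng):
        n = 150
        fit, _, _ = _unrelated_fit(rng, n)
        g = rng.binomial(1, 0.03, (n, 6)).astype(float)
        win = assoc.filter_rare(g)
        wsq = np.linspace(1, 5, win.m)
        stat1 = assoc.skat_statistic(win, wsq, fit.resid_proj)
        p1, _ = assoc.skat_pvalue(stat1, win, wsq, fit)
        stat2 = assoc.skat_statistic(win, 7.0 * wsq, fit.resid_proj)
        p2, _ = assoc.skat_pvalue(stat2, win, 7.0 * wsq, fit)
        assert p1 == pytest.approx(p2, rel=1e-7)
        b1 = assoc.burden_test(win, wsq, fit, "w")
        b2 = assoc.burden_test(win, 7.0 * wsq, fit, "w")
        assert b1.p_value == pytest.approx(b2.p_value, rel=1e-10)

    def test_duplicated_columns_with_halved_weights_leave_burden_unchanged(
            self, rng):
        n = 120
        fit, _, _ = _unrelated_fit(rng, n)
        g = rng.binomial(1, 0.03, (n, 3)).astype(float)
        win = assoc.filter_rare(g)
        w = np.array([1.0, 2.0, 3.0])[: win.m]
        base = assoc.burden_test(win, w, fit, "w")
        gdup = np.column_stack([win.G, win.G[:, :1]])
        windup = assoc.GenotypeWindow(gdup, np.r_[win.mafs, win.mafs[:1]],
                                      np.arange(win.m + 1))
        wdup = np.r_[w, w[:1]]
        wdup[0] *= 0.5
        wdup[-1] *= 0.5
        dup = assoc.burden_test(windup, wdup, fit, "w")
        assert dup.p_value == pytest.approx(base.p_value, rel=1e-10)

    def test_burden_degenerate_when_projected_out(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = rng.standard_normal(n)
        fit = fit_null(y, X, np.eye(n))
        # burden proportional to a design column: P b = 0
        g = np.tile(np.arange(n, dtype=float)[:, None] / (50 * n), (1, 1))
        win = assoc.GenotypeWindow(g, np.array([0.01]), np.array([0]))
        res = assoc.burden_test(win, np.ones(1), fit, "w")
        assert res.p_value == 1.0 and res.flag == "degenerate"


class TestOracles:
    def test_burden_matches_linear_regression(self, rng):
        """On unrelated samples the mixed-model burden test reduces to the
        classical regression test of the collapsed burden: the statistic
        equals the OLS score statistic and the p-value equals the exact
        regression (t-test) p-value, which the 1-df chi-square approaches
        asymptotically."""
        n = 500
        fit, y, X = _unrelated_fit(rng, n, p=3)
        g = rng.binomial(2, 0.02, (n, 7)).astype(float)
        win = assoc.filter_rare(g)
        w = np.ones(win.m)
        res = assoc.burden_test(win, w, fit, "w")
        b = win.G @ w
        H = X @ np.linalg.solve(X.T @ X, X.T)
        r = y - H @ y
        s2 = float(r @ r) / (n - X.shape[1])
        bres = b - H @ b
        stat_oracle = float(b @ r) ** 2 / (s2 * float(b @ bres))
        assert res.statistic == pytest.approx(stat_oracle, abs=1e-6)
        import statsmodels.api as sm
        ols = sm.OLS(y, np.column_stack([X, b])).fit()
        assert res.p_value == pytest.approx(ols.pvalues[-1], rel=1e-6)
        assert res.p_value == pytest.approx(chi2.sf(stat_oracle, 1), abs=2e-3)

    def test_skat_p_matches_permutation_null(self, rng):
        """Analytic kernel p-values agree with an empirical permutation null
        on an unrelated, intercept-only cohort (a deeper sweep runs in the
        acceptance suite)."""
        n, m, n_perm = 150, 5, 4000
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        fit = fit_null(y, X, np.eye(n))
        g = rng.binomial(2, rng.uniform(0.01, 0.04, m), (n, m)).astype(float)
        win = assoc.filter_rare(g)
        wsq = assoc.variance_weights("SKAT", win.mafs)
        stat = assoc.skat_statistic(win, wsq, fit.resid_proj)
        p, _ = assoc.skat_pvalue(stat, win, wsq, fit)
        resid = fit.resid_proj
        perms = np.stack([rng.permutation(resid) for _ in range(n_perm)])
        stats = ((perms @ win.G) ** 2) @ wsq
        p_perm = float(np.mean(stats >= stat))
        se = np.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 3 * se + 0.005


class TestBonferroni:
    def test_genomewide_scale_threshold(self):
        alpha, neglog = assoc.bonferroni_threshold(658631, 0.05)
        assert alpha == pytest.approx(7.59e-08, rel=1e-3)
        assert neglog == pytest.approx(7.12, abs=0.005)

    def test_single_test_keeps_fwer(self):
        alpha, _ = assoc.bonferroni_threshold(1, 0.05)
        assert alpha == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(0)
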