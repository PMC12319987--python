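import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from latnet import (
    bartlett_sphericity,
    cfa_fit,
    doornik_hansen,
    efa_principal_factors,
    kmo,
    parallel_analysis,
    vif,
)
from latnet.factors import _cfa_sigma, _fml, reduced_eigenvalues


def corr2(r):
    return np.array([[1.0, r], [r, 1.0]])


class TestBartlett:
    def test_identity_matrix(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("p,expected_df", [(8, 28), (4, 6)])
    def test_degrees_of_freedom(self, p, expected_df):
        R = np.eye(p) * 0.9 + 0.1
        _, df, _ = bartlett_sphericity(R, n=300)
        assert df == expected_df

    def test_closed_form_2x2(self):
        # chi2 = -(100 - 1 - 9/6) ln(1 - 0.25) = -97.5 ln 0.75
        chi2, df, p = bartlett_sphericity(corr2(0.5), n=100)
        assert chi2 == pytest.approx(-97.5 * np.log(0.75))
        assert df == 1

    def test_reordering_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.normal(0, 1, (50, 4))
        R = np.corrcoef(A, rowvar=False)
        chi2_a, *_ = bartlett_sphericity(R, n=50)
        perm = [2, 0, 3, 1]
        chi2_b, *_ = bartlett_sphericity(R[np.ix_(perm, perm)], n=50)
        assert chi2_a == pytest.approx(chi2_b)

    def test_singular_matrix_rejected(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            bartlett_sphericity(R, n=50)


class TestKMO:
    @given(st.floats(-0.95, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_two_variable_identity(self, r):
        """For p = 2 the partial equals the marginal correlation, so KMO = 1/2."""
        if abs(r) < 1e-6:
            return  # degenerate 0/0 case
        overall, per = kmo(corr2(r))
        assert overall == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(per, 0.5)

    def test_three_by_three_against_partial_correlation_oracle(self):
        """Anti-image entries equal pairwise partial correlations computed
        independently by residualizing on the remaining variable."""
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (200, 3))
        X[:, 1] += 0.5 * X[:, 0]
        X[:, 2] += 0.3 * X[:, 1]
        R = np.corrcoef(X, rowvar=False)
        overall, per = kmo(R)

        def partial(i, j, k):
            beta_i = np.polyfit(X[:, k], X[:, i], 1)
            beta_j = np.polyfit(X[:, k], X[:, j], 1)
            ri = X[:, i] - np.polyval(beta_i, X[:, k])
            rj = X[:, j] - np.polyval(beta_j, X[:, k])
            return np.corrcoef(ri, rj)[0, 1]

        r2 = q2 = 0.0
        for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            r2 += 2 * R[i, j] ** 2
            q2 += 2 * partial(i, j, k) ** 2
        assert overall == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(0, 1, (60, 5))
            overall, per = kmo(np.corrcoef(X, rowvar=False))
            assert 0.0 <= overall <= 1.0
            assert np.all((per >= 0) & (per <= 1))


class TestVIF:
    def test_orthogonal_variables(self):
        n = 40
        X = np.zeros((n, 3))
        X[:, 0] = np.sin(np.arange(n))
        # Gram–Schmidt to make columns exactly orthogonal and centered
        rng = np.random.default_rng(3)
        for j in range(1, 3):
            v = rng.normal(0, 1, n)
            for i in range(j):
                u = X[:, i] - X[:, i].mean()
                w = v - v.mean()
                v = v - (w @ u) / (u @ u) * u
            X[:, j] = v
        X -= X.mean(axis=0)
        out = vif(pd.DataFrame(X, columns=list("abc")))
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-8)

    def test_closed_form_r06(self):
        # exact sample correlation 0.6 via Gram–Schmidt construction
        n = 50
        rng = np.random.default_rng(4)
        z1 = rng.normal(0, 1, n)
        z1 = (z1 - z1.mean()) / z1.std()
        e = rng.normal(0, 1, n)
        e -= e.mean()
        e -= (e @ z1) / (z1 @ z1) * z1
        e /= e.std()
        x2 = 0.6 * z1 + np.sqrt(1 - 0.36) * e
        out = vif(pd.DataFrame({"a": z1, "b": x2}))
        assert out["a"] == pytest.approx(1 / (1 - 0.36), abs=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (80, 3))
        X[:, 2] += 0.7 * X[:, 0]
        ours = vif(pd.DataFrame(X, columns=list("abc"))).to_numpy()
        D = sm.add_constant(X)
        ref = [variance_inflation_factor(D, j) for j in (1, 2, 3)]
        assert np.allclose(ours, ref, atol=1e-8)

    def test_perfect_collinearity_is_infinite(self):
        x = np.linspace(0, 1, 30)
        out = vif(pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.sin(x)}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])


class TestDoornikHansen:
    def test_df_is_twice_p(self):
        rng = np.random.default_rng(6)
        for p in (2, 4, 8):
            _, df, _ = doornik_hansen(rng.normal(0, 1, (200, p)))
            assert df == 2 * p

    def test_size_under_normality(self):
        """Rejection rate at alpha=.05 for multivariate normal data."""
        rng = np.random.default_rng(7)
        reps, hits = 400, 0
        for _ in range(reps):
            X = rng.standard_normal((500, 4))
            _, _, p = doornik_hansen(X)
            if p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_power_against_exponential(self):
        rng = np.random.default_rng(8)
        reps, hits = 100, 0
        for _ in range(reps):
            X = rng.exponential(1.0, (500, 4))
            _, _, p = doornik_hansen(X)
            if p < 0.05:
                hits += 1
        assert hits / reps > 0.95

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(np.linalg.LinAlgError):
            doornik_hansen(X)


class TestEFA:
    def test_identity_matrix_has_no_structure(self):
        m = efa_principal_factors(np.eye(6), n_factors=2)
        assert np.allclose(m.loadings.to_numpy(), 0.0, atol=1e-6)
        assert np.allclose(m.communalities.to_numpy(), 0.0, atol=1e-6)

    def test_variance_proportions_of_reported_eigenvalues(self):
        # retained eigenvalues 1.38 and 1.02 split 57.5% / 42.5%
        eig = np.array([1.38, 1.02])
        prop = eig / eig.sum()
        assert prop[0] == pytest.approx(0.575)
        assert prop[1] == pytest.approx(0.425)
        assert round(prop[0], 2) == 0.57 or round(prop[0], 2) == 0.58

    def test_one_factor_population_recovery(self):
        lam = np.array([0.8, 0.7, 0.6])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        m = efa_principal_factors(R, n_factors=1)
        got = m.loadings.to_numpy()[:, 0]
        if got[0] < 0:
            got = -got
        assert np.allclose(got, lam, atol=1e-3)

    def test_two_factor_population_recovery(self):
        """Bipolar two-factor structure recovered from its population R."""
        L = np.array(
            [
                [0.7, -0.3],
                [0.3, 0.1],
                [0.3, 0.1],
                [0.3, 0.25],
                [-0.4, -0.7],
                [-0.5, 0.1],
                [-0.4, 0.5],
            ]
        )
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        m = efa_principal_factors(R, n_factors=2)
        # compare factor subspaces via the reproduced reduced matrix
        got = m.loadings.to_numpy()
        assert np.allclose(got @ got.T - np.diag(np.diag(got @ got.T)),
                           L @ L.T - np.diag(np.diag(L @ L.T)), atol=0.05)
        assert m.proportion_variance.sum() == pytest.approx(1.0)

    def test_invalid_factor_counts(self):
        with pytest.raises(ValueError):
            efa_principal_factors(np.eye(4), n_factors=0)
        with pytest.raises(ValueError):
            efa_principal_factors(np.eye(4), n_factors=4)


class TestParallelAnalysis:
    def test_retained_bounded_by_p(self):
        obs = np.array([5.0, 3.0, 2.0, 1.0])
        k = parallel_analysis(n=200, p=4, reps=100, seed=0, observed_eigenvalues=obs)
        assert 0 <= k <= 4

    def test_null_data_retains_nothing(self):
        rng = np.random.default_rng(9)
        zero_count = 0
        outer = 20
        for i in range(outer):
            X = rng.standard_normal((1000, 8))
            obs = reduced_eigenvalues(np.corrcoef(X, rowvar=False))
            k = parallel_analysis(
                n=1000, p=8, reps=100, seed=100 + i, observed_eigenvalues=obs
            )
            if k == 0:
                zero_count += 1
        assert zero_count / outer >= 0.90

    def test_strong_single_factor_retains_one(self):
        rng = np.random.default_rng(10)
        ones = 0
        outer = 20
        for i in range(outer):
            f = rng.standard_normal(1000)
            X = 0.9 * f[:, None] + np.sqrt(1 - 0.81) * rng.standard_normal((1000, 8))
            obs = reduced_eigenvalues(np.corrcoef(X, rowvar=False))
            k = parallel_analysis(
                n=1000, p=8, reps=100, seed=200 + i, observed_eigenvalues=obs
            )
            if k == 1:
                ones += 1
        assert ones / outer >= 0.95

    def test_deterministic_under_seed(self):
        obs = np.array([2.0, 0.5, 0.1, 0.0])
        k1 = parallel_analysis(500, 4, 150, 3, obs)
        k2 = parallel_analysis(500, 4, 150, 3, obs)
        assert k1 == k2


def simulate_cfa_data(rng, n, loadings, psi, phi=0.0):
    """Draw indicator data from a two-factor simple-structure model."""
    p = len(loadings)
    half = p // 2
    Phi = np.array([[1.0, phi], [phi, 1.0]])
    F = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Phi).T
    factor_of = np.array([0] * half + [1] * (p - half))
    X = F[:, factor_of] * loadings + rng.standard_normal((n, p)) * np.sqrt(psi)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])


SPEC4 = {"x0": "f1", "x1": "f1", "x2": "f2", "x3": "f2"}


class TestCFA:
    def test_df_two_for_four_indicators(self):
        rng = np.random.default_rng(11)
        data = simulate_cfa_data(rng, 300, np.array([0.8, 0.6, 0.7, 0.5]), 0.5)
        m = cfa_fit(data, SPEC4)
        assert m.df == 2
        m_free = cfa_fit(data, SPEC4, factor_covariance="free")
        assert m_free.df == 1

    def test_exact_model_covariance_is_saturated_fit(self):
        """Data transformed to have sample covariance equal to the
        model-implied covariance: T = 0, CFI = 1, RMSEA = 0, SRMR = 0."""
        rng = np.random.default_rng(12)
        lam = np.array([0.8, 0.6, 0.7, 0.5])
        psi = 1 - lam**2
        Sigma = _cfa_sigma(lam, psi, 0.0, np.array([0, 0, 1, 1]), 2)
        Z = rng.standard_normal((400, 4))
        Zc = Z - Z.mean(axis=0)
        # whiten then color so the sample covariance is exactly Sigma
        S_emp = np.cov(Zc, rowvar=False, ddof=1)
        W = np.linalg.cholesky(np.linalg.inv(S_emp))
        X = Zc @ W @ np.linalg.cholesky(Sigma).T
        m = cfa_fit(pd.DataFrame(X, columns=["x0", "x1", "x2", "x3"]), SPEC4)
        assert m.chi2 == pytest.approx(0.0, abs=1e-4)
        assert m.cfi == pytest.approx(1.0, abs=1e-6)
        assert m.rmsea == pytest.approx(0.0, abs=1e-4)
        assert m.srmr == pytest.approx(0.0, abs=1e-4)
        # loadings are identified only up to the within-factor product (two
        # indicators per orthogonal factor): the product of standardized
        # loadings must equal the indicator correlation
        got = m.loadings.to_numpy().sum(axis=1)
        R = Sigma / np.sqrt(np.outer(np.diag(Sigma), np.diag(Sigma)))
        assert got[0] * got[1] == pytest.approx(R[0, 1], abs=1e-4)
        assert got[2] * got[3] == pytest.approx(R[2, 3], abs=1e-4)

    def test_discrepancy_matches_independent_optimizer(self):
        """F_ML minimum agrees with a general-purpose Nelder–Mead search
        over the same parameterization (tolerance 1e-4)."""
        rng = np.random.default_rng(13)
        # misspecified: data generated with correlated factors, fit with
        # the covariance fixed to zero
        data = simulate_cfa_data(
            rng, 150, np.array([0.8, 0.6, 0.7, 0.5]), 0.5, phi=-0.4
        )
        m = cfa_fit(data, SPEC4)
        S = np.cov(data.to_numpy(), rowvar=False, ddof=1)
        factor_of = np.array([0, 0, 1, 1])

        def obj(theta):
            lam, logpsi = theta[:4], theta[4:]
            return _fml(S, _cfa_sigma(lam, np.exp(logpsi), 0.0, factor_of, 2))

        best = np.inf
        for s in range(8):
            r2 = np.random.default_rng(s)
            x0 = np.concatenate([r2.uniform(0.2, 1.0, 4), np.log(r2.uniform(0.2, 1.0, 4))])
            res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                    options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert m.discrepancy == pytest.approx(best, abs=1e-4)

    def test_parameter_recovery_large_n(self):
        """The identified standardized-loading products recover the
        generating within-factor correlations at n = 2000, and a correctly
        specified model's T sits inside the chi2(2) 95% band."""
        rng = np.random.default_rng(14)
        lam = np.array([0.8, 0.6, 0.7, 0.5])
        band = stats.chi2.ppf(0.95, 2)
        in_band = 0
        for rep in range(10):
            data = simulate_cfa_data(rng, 2000, lam, 1 - lam**2)
            m = cfa_fit(data, SPEC4)
            got = m.loadings.to_numpy().sum(axis=1)
            assert got[0] * got[1] == pytest.approx(lam[0] * lam[1], abs=0.05)
            assert got[2] * got[3] == pytest.approx(lam[2] * lam[3], abs=0.05)
            if m.chi2 <= band:
                in_band += 1
        # correctly specified model: T ~ chi2(2), so ~95% of draws in band
        assert in_band >= 8

    def test_validation(self):
        rng = np.random.default_rng(15)
        data = simulate_cfa_data(rng, 100, np.array([0.8, 0.6, 0.7, 0.5]), 0.5)
        with pytest.raises(KeyError):
            cfa_fit(data, {"nope": "f1"})
        with pytest.raises(ValueError):
            cfa_fit(data, SPEC4, factor_covariance="banana")
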