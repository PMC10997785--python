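import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from heritpart.mixed_model import (
    FixedEffect,
    ModelSpec,
    build_design,
    h2_from_fit,
    record_covariances,
    reml_fit,
    reml_fit_design,
    restricted_loglik,
)


def contrast_reml_oracle(y, X, structures, sigma2):
    """Restricted likelihood via an explicit error-contrast basis.

    Independent route: project y onto an orthonormal null-space basis K of
    X' and evaluate the Gaussian log-density of K'y ~ N(0, K'VK).
    """
    n, p = X.shape
    V = sigma2[-1] * np.eye(n)
    for s2, G in zip(sigma2[:-1], structures):
        V += s2 * G
    q, _ = np.linalg.qr(X, mode="complete")
    K = q[:, p:]
    S = K.T @ V @ K
    resid = K.T @ y
    sign, logdet = np.linalg.slogdet(S)
    assert sign > 0
    return float(
        -0.5 * (logdet + resid @ np.linalg.solve(S, resid)
                + (n - p) * np.log(2 * np.pi))
    )


def balanced_oneway_reml(y, groups):
    """Closed-form REML for a balanced one-way random-effects layout."""
    df = pd.DataFrame({"y": y, "g": groups})
    k = df["g"].nunique()
    m = len(df) // k
    gm = df.groupby("g")["y"].mean()
    msb = m * ((gm - df["y"].mean()) ** 2).sum() / (k - 1)
    msw = ((df["y"] - df["g"].map(gm)) ** 2).sum() / (k * (m - 1))
    return max((msb - msw) / m, 0.0), msw


def make_oneway(rng, k=12, m=6, sg=1.5, se=1.0):
    groups = np.repeat(np.arange(k), m)
    y = (np.sqrt(sg) * rng.normal(size=k))[groups] + np.sqrt(se) * rng.normal(
        size=k * m
    )
    return y, groups


class TestBuildDesign:
    def phenos(self):
        return pd.DataFrame({
            "id": ["a", "a", "b"],
            "y": [1.0, 2.0, 3.0],
            "sex": ["M", "M", "F"],
            "age": [1.0, 2.0, 3.0],
        })

    def test_repeated_records_share_a_W_column(self):
        spec = ModelSpec(trait="y", random_effects=["sex"])
        d = build_design(spec, self.phenos(), ["a", "b"])
        assert d.W.shape == (3, 2)
        np.testing.assert_array_equal(d.W.sum(axis=1), [1, 1, 1])
        np.testing.assert_array_equal(d.W.sum(axis=0), [2, 1])

    def test_two_level_factor_gives_one_column(self):
        spec = ModelSpec(trait="y", fixed_effects=[FixedEffect("sex", "categorical")],
                         random_effects=["sex"])
        d = build_design(spec, self.phenos(), ["a", "b"])
        assert d.x_names == ["intercept", "sex[M]"]

    def test_quadratic_expansion(self):
        spec = ModelSpec(trait="y",
                         fixed_effects=[FixedEffect("age", "continuous", degree=2)],
                         random_effects=["sex"])
        d = build_design(spec, self.phenos(), ["a", "b"])
        np.testing.assert_array_equal(d.X[:, 1], [1, 2, 3])
        np.testing.assert_array_equal(d.X[:, 2], [1, 4, 9])

    def test_missing_covariate_records_dropped_with_count(self):
        ph = self.phenos()
        ph.loc[1, "age"] = np.nan
        spec = ModelSpec(trait="y", fixed_effects=[FixedEffect("age")],
                         random_effects=["sex"])
        d = build_design(spec, ph, ["a", "b"])
        assert d.n_dropped == 1 and len(d.y) == 2

    def test_aliased_columns_are_named(self):
        ph = self.phenos()
        ph["age2"] = ph["age"]
        spec = ModelSpec(trait="y",
                         fixed_effects=[FixedEffect("age"), FixedEffect("age2")],
                         random_effects=["sex"])
        with pytest.raises(ValueError, match="age2"):
            build_design(spec, ph, ["a", "b"])


class TestRestrictedLoglik:
    def test_identity_covariance_closed_form(self):
        # X = intercept, V = I, y = 0: ll = -((n-p)/2) log(2 pi)
        y = np.zeros(3)
        X = np.ones((3, 1))
        ll = restricted_loglik(y, X, [], [1.0])
        assert ll == pytest.approx(-1.0 * np.log(2 * np.pi))

    def test_scaling_identity(self, rng):
        n = 20
        G = rng.normal(size=(n, n))
        G = G @ G.T / n
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        s = [0.7, 0.9]
        c2 = 2.5
        ll = restricted_loglik(y, X, [G], s)
        ll_scaled = restricted_loglik(np.sqrt(c2) * y, X, [G],
                                      [c2 * s[0], c2 * s[1]])
        # Jacobian of the contrast transform: -(n - p)/2 log(c2)
        assert ll_scaled == pytest.approx(ll - 0.5 * (n - 2) * np.log(c2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_contrast_basis_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        A = rng.normal(size=(n, n))
        G1 = A @ A.T / n
        B = rng.normal(size=(n, n))
        G2 = B @ B.T / n
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        sigma2 = [0.5, 0.3, 1.2]
        ll = restricted_loglik(y, X, [G1, G2], sigma2)
        assert ll == pytest.approx(
            contrast_reml_oracle(y, X, [G1, G2], sigma2), abs=1e-8
        )

    def test_reference_level_invariance(self, rng):
        # recoding a categorical covariate leaves the criterion unchanged
        n = 30
        grp = rng.integers(0, 3, size=n)
        y = rng.normal(size=n) + grp * 0.5
        X1 = np.column_stack([np.ones(n), grp == 1, grp == 2]).astype(float)
        X2 = np.column_stack([np.ones(n), grp == 0, grp == 1]).astype(float)
        G = np.eye(n)
        for s in ([0.5, 0.8], [1.0, 0.2]):
            assert restricted_loglik(y, X1, [G], s) == pytest.approx(
                restricted_loglik(y, X2, [G], s), abs=1e-9
            )


class TestRemlFit:
    def test_balanced_oneway_matches_closed_form(self, rng):
        y, groups = make_oneway(rng)
        ph = pd.DataFrame({"id": [f"i{k}" for k in range(len(y))],
                           "y": y, "grp": groups.astype(str)})
        spec = ModelSpec(trait="y", random_effects=["grp"])
        d = build_design(spec, ph, ph["id"].tolist())
        labels, structures = record_covariances(spec, d)
        fit = reml_fit(d.y, d.X, structures, labels)
        sg, se = balanced_oneway_reml(y, groups)
        assert fit.converged
        assert fit.sigma2["grp"] == pytest.approx(sg, abs=1e-6)
        assert fit.sigma2["residual"] == pytest.approx(se, abs=1e-6)

    def test_balanced_oneway_cross_checked_against_statsmodels(self, rng):
        import statsmodels.api as sm

        y, groups = make_oneway(rng, k=10, m=5)
        fit_sm = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=True)
        sg, se = balanced_oneway_reml(y, groups)
        assert float(np.asarray(fit_sm.cov_re)[0, 0]) == pytest.approx(sg, rel=1e-4)
        assert float(fit_sm.scale) == pytest.approx(se, rel=1e-4)

    def test_zero_variance_component_hits_floor_and_is_flagged(self):
        # truth has no group variance; across seeds the estimate is pinned
        # at the floor in about half the replicates and always stays small
        n, k = 200, 20
        groups = np.repeat(np.arange(k), n // k)
        Z = np.eye(k)[groups]
        G = Z @ Z.T
        X = np.ones((n, 1))
        floored = 0
        for seed in range(6):
            y = np.random.default_rng(seed).normal(size=n)
            fit = reml_fit(y, X, [G], ["grp"])
            assert fit.sigma2["grp"] < 0.15 * fit.total_variance
            if fit.constraint_flags["grp"]:
                floored += 1
                assert np.isnan(fit.se("grp"))
        assert floored >= 1

    def test_nested_models_never_lose_loglik(self, rng):
        n = 120
        A = rng.normal(size=(n, n))
        G1 = A @ A.T / n
        B = rng.normal(size=(n, n))
        G2 = B @ B.T / n
        y = rng.multivariate_normal(np.zeros(n), 0.5 * G1 + np.eye(n))
        X = np.ones((n, 1))
        fit1 = reml_fit(y, X, [G1], ["a"])
        fit2 = reml_fit(y, X, [G1, G2], ["a", "b"],
                        start=[fit1.sigma2["a"], 1e-4,
                               fit1.sigma2["residual"]])
        assert fit2.loglik_restricted >= fit1.loglik_restricted - 1e-6

    def test_permutation_invariance(self, rng):
        n = 60
        A = rng.normal(size=(n, n))
        G = A @ A.T / n
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        fit = reml_fit(y, X, [G], ["g"])
        fit_p = reml_fit(y[perm], X[perm], [G[np.ix_(perm, perm)]], ["g"])
        assert fit_p.loglik_restricted == pytest.approx(
            fit.loglik_restricted, abs=1e-6
        )
        assert fit_p.sigma2["g"] == pytest.approx(fit.sigma2["g"], rel=1e-4,
                                                  abs=1e-8)

    def test_parameter_recovery_simulated_animal_model(self):
        # 50 replicates, n = 500, 2000 SNPs, h2 = 0.4: mean within 2 MC SEs
        ests = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n, m = 500, 2000
            p = rng.uniform(0.2, 0.8, size=m)
            d = rng.binomial(2, p, size=(n, m)).astype(float)
            z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
            G = z @ z.T / m
            bv = z[:, :300] @ rng.normal(size=300)
            bv *= np.sqrt(0.4) / bv.std()
            y = bv + np.sqrt(0.6) * rng.normal(size=n)
            fit = reml_fit(y, np.ones((n, 1)), [G], ["g"])
            ests.append(fit.sigma2["g"] / fit.total_variance)
        ests = np.array(ests)
        mcse = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.4) < 2 * mcse + 1e-9


class TestH2FromFit:
    def test_simple_ratio(self, rng):
        n = 80
        G = np.eye(n)
        fit = reml_fit(rng.normal(size=n), np.ones((n, 1)), [G], ["g"])
        h2, se = h2_from_fit(fit, ["g"])
        assert h2 == pytest.approx(
            fit.sigma2["g"] / fit.total_variance
        )

    def test_sum_ratio_equals_sum_of_ratios(self, rng):
        n = 100
        A = rng.normal(size=(n, n))
        G1 = A @ A.T / n
        B = rng.normal(size=(n, n))
        G2 = B @ B.T / n
        y = rng.multivariate_normal(np.zeros(n), 0.4 * G1 + 0.2 * G2 + np.eye(n))
        fit = reml_fit(y, np.ones((n, 1)), [G1, G2], ["a", "b"])
        h2a, _ = h2_from_fit(fit, ["a"])
        h2b, _ = h2_from_fit(fit, ["b"])
        h2ab, _ = h2_from_fit(fit, ["a", "b"])
        assert h2ab == pytest.approx(h2a + h2b, abs=1e-12)

    def test_delta_method_matches_finite_differences(self, rng):
        n = 100
        A = rng.normal(size=(n, n))
        G = A @ A.T / n
        y = rng.multivariate_normal(np.zeros(n), 0.6 * G + np.eye(n))
        fit = reml_fit(y, np.ones((n, 1)), [G], ["g"])
        h2, se = h2_from_fit(fit, ["g"])
        theta = np.array([fit.sigma2["g"], fit.sigma2["residual"]])

        def ratio(t):
            return t[0] / t.sum()

        eps = 1e-6
        grad = np.array([
            (ratio(theta + eps * e) - ratio(theta - eps * e)) / (2 * eps)
            for e in np.eye(2)
        ])
        C = fit.sampling_cov.to_numpy()
        assert se == pytest.approx(float(np.sqrt(grad @ C @ grad)), abs=1e-6)

    def test_zero_total_variance_is_error(self):
        from heritpart.mixed_model import VarianceComponentFit

        fit = VarianceComponentFit(
            labels=["g", "residual"], sigma2={"g": 0.0, "residual": 0.0},
            loglik_restricted=0.0, sampling_cov=None, converged=True,
            n_iterations=1, constraint_flags={}, n_records=10, n_fixed=1,
        )
        with pytest.raises(ValueError, match="total variance"):
            h2_from_fit(fit, ["g"])
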