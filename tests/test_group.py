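"""Outlier gates, Shapiro-gated correlations, and the popularity
regression ladder with its log-transform bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegsync.group import (
    AnalysisError,
    bonferroni_threshold,
    compare_nested,
    fit_popularity_model,
    gated_correlation,
    mahalanobis_screen,
    remove_univariate_outliers,
)


def _scaled_sample(rng, n, mean, sd):
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestUnivariateOutliers:
    def test_mega_hit_removed_by_3sd_gate(self):
        """23 streams ~ N(3.32, 2.29) plus one mega-hit at 20.06 million:
        the full-sample stats (mean ≈ 4.02, SD ≈ 4.08) put only the
        mega-hit past 3 SD, leaving 23 songs."""
        rng = np.random.default_rng(0)
        body = _scaled_sample(rng, 23, 3.32, 2.29)
        x = np.append(body, 20.06)
        rep = remove_univariate_outliers(x, k=3.0)
        assert rep.mean == pytest.approx(4.02, abs=0.02)
        assert rep.sd == pytest.approx(4.08, abs=0.06)
        assert list(rep.removed_index) == [23]
        assert len(rep.kept) == 23

    def test_all_equal_nothing_removed(self):
        rep = remove_univariate_outliers(np.full(10, 7.0))
        assert len(rep.removed_index) == 0

    def test_single_pass_does_not_iterate(self):
        """A second extreme value that only crosses 3 SD after the first
        removal stays in: the gate runs once on the full sample."""
        x = np.array([0.0] * 20 + [5.0, 50.0])
        rep = remove_univariate_outliers(x)
        assert list(rep.removed_index) == [21]
        # brute-force single-pass oracle
        m, s = x.mean(), x.std(ddof=1)
        oracle = np.flatnonzero(np.abs(x - m) > 3 * s)
        assert list(rep.removed_index) == list(oracle)
        # after removal the 5.0 would now exceed 3 SD of the remainder
        rest = np.delete(x, 21)
        assert abs(5.0 - rest.mean()) > 3 * rest.std(ddof=1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        scale=st.floats(0.01, 1000.0, allow_nan=False),
    )
    def test_scale_equivariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        x[0] += 8.0
        a = remove_univariate_outliers(x)
        b = remove_univariate_outliers(scale * x)
        assert list(a.removed_index) == list(b.removed_index)

    def test_too_few_values_rejected(self):
        with pytest.raises(AnalysisError):
            remove_univariate_outliers([1.0, 2.0])


class TestMahalanobis:
    def test_mean_row_has_zero_distance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 3))
        x[0] = x.mean(axis=0)
        # recentre so row 0 is exactly the mean after inclusion
        x[0] = (x[1:].sum(axis=0)) / 49.0
        x[0] = x.mean(axis=0)  # fixed point within float tolerance
        flags, d2 = mahalanobis_screen(x)
        assert d2[0] == pytest.approx(0.0, abs=1e-10)
        assert not flags[0]

    def test_gross_outlier_flagged_with_max_distance(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.standard_normal((1000, 2)), [[10.0, 10.0]]])
        flags, d2 = mahalanobis_screen(x)
        assert flags[-1]
        assert d2.argmax() == 1000

    def test_identity_covariance_reduces_to_euclidean(self):
        """After whitening, squared Mahalanobis distances equal squared
        Euclidean distances from the mean."""
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((200, 3))
        raw -= raw.mean(axis=0)
        # whiten: sample covariance becomes exactly identity
        cov = np.cov(raw, rowvar=False)
        L = np.linalg.cholesky(np.linalg.inv(cov))
        x = raw @ L
        flags, d2 = mahalanobis_screen(x)
        np.testing.assert_allclose(d2, (x**2).sum(axis=1), rtol=1e-8)

    def test_singular_covariance_advises(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(AnalysisError, match="singular"):
            mahalanobis_screen(x)


class TestGatedCorrelation:
    def test_family_of_8_reproduces_printed_threshold(self):
        thr = bonferroni_threshold(0.05, 8)
        assert thr == pytest.approx(0.00625)
        assert round(thr, 3) == 0.006

    def test_identity_picks_pearson_r_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        rep = gated_correlation(x, x.copy(), pair="x~x")
        assert rep.method == "pearson"
        assert rep.statistic == pytest.approx(1.0)
        assert rep.significant

    def test_heavy_tailed_variable_forces_kendall(self):
        """Log-normal marginals fail Shapiro essentially always at n=50,
        so the Kendall branch must be selected regardless of x."""
        rng = np.random.default_rng(5)
        picked = []
        for _ in range(100):
            x = rng.standard_normal(50)
            y = np.exp(rng.standard_normal(50) * 1.5)
            picked.append(gated_correlation(x, y).method)
        assert np.mean([m == "kendall" for m in picked]) > 0.95

    def test_bivariate_normal_selects_pearson_at_shapiro_rate(self):
        """Both gates pass ~(1-0.05)^2 of the time for normal data."""
        rng = np.random.default_rng(6)
        picked = []
        for _ in range(1000):
            x = rng.standard_normal(50)
            y = 0.5 * x + rng.standard_normal(50)
            picked.append(gated_correlation(x, y).method)
        rate = np.mean([m == "pearson" for m in picked])
        assert 0.85 <= rate <= 0.95

    def test_constant_variable_rejected(self):
        with pytest.raises(AnalysisError, match="constant"):
            gated_correlation(np.ones(10), np.arange(10.0))


class TestPopularityModel:
    def _frame(self, y, synch, single=None):
        d = {"streams": y, "synchrony": synch}
        if single is not None:
            d["single"] = single
        return pd.DataFrame(d)

    def test_noiseless_recovery_exact(self):
        x = np.linspace(20, 40, 24)
        y = 0.5 + 0.7 * x
        rep = fit_popularity_model(self._frame(y, x), "streams", ["synchrony"])
        assert rep.transform == "none"
        assert rep.params["synchrony"]["b"] == pytest.approx(0.7, abs=1e-9)
        assert rep.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_log_multiplier_matches_lognormal_mean_oracle(self):
        """On the log scale the reported multiplier is exp(b + σ̂²/2),
        which reproduces the log-normal conditional mean E[y|x]."""
        rng = np.random.default_rng(7)
        n = 4000
        x = np.repeat([1.0, 2.0, 3.0, 4.0], n // 4)
        sigma = 0.5
        y = np.exp(0.3 + 0.4 * x + sigma * rng.standard_normal(n))
        rep = fit_popularity_model(
            self._frame(y, x), "streams", ["synchrony"], force_transform="log"
        )
        b = rep.params["synchrony"]["b"]
        assert rep.multipliers["synchrony"] == pytest.approx(
            np.exp(b + rep.sigma2 / 2), rel=1e-12
        )
        # predicted mean at x = 2 vs empirical mean of y there
        const = rep.params["const"]["b"]
        pred = np.exp(const + b * 2.0 + rep.sigma2 / 2)
        emp = y[x == 2.0].mean()
        assert pred == pytest.approx(emp, rel=0.05)

    def test_multiplier_reduces_to_exp_b_as_sigma_vanishes(self):
        x = np.linspace(1, 3, 30)
        rng = np.random.default_rng(8)
        y = np.exp(0.2 + 0.5 * x + 1e-4 * rng.standard_normal(30))
        rep = fit_popularity_model(
            self._frame(y, x), "streams", ["synchrony"], force_transform="log"
        )
        b = rep.params["synchrony"]["b"]
        assert rep.sigma2 < 1e-7
        assert rep.multipliers["synchrony"] == pytest.approx(np.exp(b), rel=1e-6)

    def test_skewed_residuals_trigger_log_transform(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 2, 60)
        y = np.exp(1.0 + 1.2 * x + 0.8 * rng.standard_normal(60))
        rep = fit_popularity_model(self._frame(y, x), "streams", ["synchrony"])
        assert rep.transform == "log"
        assert rep.untransformed_diagnostics is not None

    def test_perfect_collinearity_named(self):
        x = np.linspace(0, 1, 20)
        frame = pd.DataFrame(
            {"streams": x + 1, "synchrony": x, "single": 2 * x}
        )
        with pytest.raises(AnalysisError, match="collinear"):
            fit_popularity_model(frame, "streams", ["synchrony", "single"])


class TestNestedComparison:
    def test_null_noise_column_gives_uniform_p(self):
        """Adding a pure-noise term yields F p-values that are uniform
        under the null (KS over 500 simulations)."""
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(500):
            x1 = rng.standard_normal(20)
            x2 = rng.standard_normal(20)
            y = 1.0 + 0.5 * x1 + rng.standard_normal(20)
            frame = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            base = fit_popularity_model(frame, "y", ["x1"], force_transform="none")
            ext = fit_popularity_model(
                frame, "y", ["x1", "x2"], force_transform="none"
            )
            pvals.append(compare_nested(base, ext)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_coefficient_duplicate_gives_f_zero(self):
        """A predictor exactly orthogonal to the residual leaves RSS
        unchanged: the boundary F = 0 is handled."""
        rng = np.random.default_rng(11)
        x1 = rng.standard_normal(30)
        y = 2.0 + 0.8 * x1 + rng.standard_normal(30)
        # build x2 orthogonal to [1, x1, y] so its OLS coefficient is 0
        basis = np.column_stack([np.ones(30), x1, y])
        q, _ = np.linalg.qr(basis)
        raw = rng.standard_normal(30)
        x2 = raw - q @ (q.T @ raw)
        frame = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        base = fit_popularity_model(frame, "y", ["x1"], force_transform="none")
        ext = fit_popularity_model(frame, "y", ["x1", "x2"], force_transform="none")
        f_stat, p = compare_nested(base, ext)
        assert f_stat == pytest.approx(0.0, abs=1e-6)
        assert p > 0.999

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(
            {
                "y": rng.standard_normal(20),
                "x1": rng.standard_normal(20),
                "x2": rng.standard_normal(20),
            }
        )
        a = fit_popularity_model(frame, "y", ["x1"], force_transform="none")
        b = fit_popularity_model(frame, "y", ["x2"], force_transform="none")
        with pytest.raises(AnalysisError, match="subset"):
            compare_nested(a, b)
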