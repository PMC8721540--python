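"""Global tests, equicoordinate quantiles, and the multiple contrast procedure."""

import numpy as np
import pytest
from scipy import stats

from nparrm import (
    ContrastSpec,
    DegenerateTestError,
    RMDataset,
    ats1,
    ats2,
    ats_weighted,
    covariance_psd,
    equicoordinate_quantile,
    mctp,
    tukey_contrast,
    unweighted_effects,
    wts,
    wts_weighted,
)
from nparrm.inference import mctp_global_pvalue
from nparrm.simulation import ScenarioConfig, run_study

from conftest import complete_dataset, random_missing_dataset


def _fitted(rng, n=12, d=3):
    ds = random_missing_dataset(rng, n=n, d=d, integer=False, missing_prob=0.2)
    eff = unweighted_effects(ds)
    return ds, eff, covariance_psd(ds, eff)


class TestWTS:
    def test_null_vector_gives_zero_statistic(self, rng):
        _, _, V = _fitted(rng)
        res = wts(np.full(3, 0.5), V, tukey_contrast(3), n=12)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_single_contrast_reduces_to_squared_univariate(self, rng):
        ds, eff, V = _fitted(rng, d=2)
        C = ContrastSpec(np.array([[-1.0, 1.0]]))
        res = wts(eff.p_hat, V, C, ds.n_subjects)
        c = C.C[0]
        expected = ds.n_subjects * (c @ eff.p_hat) ** 2 / (c @ V.V @ c)
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df1 == 1.0

    def test_zero_covariance_degenerate(self):
        values = np.tile([1.0, 2.0], (5, 1))
        ds = RMDataset(values, np.ones((5, 2), dtype=int))
        eff = unweighted_effects(ds)
        V = covariance_psd(ds, eff)
        with pytest.raises(DegenerateTestError):
            wts(eff.p_hat, V, tukey_contrast(2), 5)


class TestATS:
    def test_null_vector_gives_zero_statistic(self, rng):
        _, _, V = _fitted(rng)
        for fn in (ats1, ats2):
            res = fn(np.full(3, 0.5), V, tukey_contrast(3), n=12)
            assert res.statistic == pytest.approx(0.0, abs=1e-20)
            assert res.p_value == pytest.approx(1.0)

    def test_df_equals_rank_when_covariance_proportional_to_projection(self):
        C = tukey_contrast(4)
        res = ats1(np.array([0.3, 0.4, 0.6, 0.7]), 0.37 * C.M, C, n=20)
        # tr(M V) = 0.37 rank(M), tr(MVMV) = 0.37^2 rank(M) -> f = rank(M) = 3
        assert res.df1 == pytest.approx(3.0, rel=1e-10)

    def test_version2_is_version1_over_df(self, rng):
        """A_{n,2} = A_n / f identically."""
        for _ in range(10):
            ds, eff, V = _fitted(rng, n=15, d=4)
            C = tukey_contrast(4)
            a1 = ats1(eff.p_hat, V, C, ds.n_subjects)
            a2 = ats2(eff.p_hat, V, C, ds.n_subjects)
            assert a2.statistic == pytest.approx(a1.statistic / a1.df1, rel=1e-10)
            assert a2.df1 == pytest.approx(a1.df1)
            assert a2.df2 == pytest.approx((ds.n_subjects - 1) * a1.df1)

    def test_f_reference_approaches_chisquare_for_large_n(self, rng):
        """F(f, (n-1) f) converges to chi2(f)/f, so the two p-values merge."""
        ds, eff, V = _fitted(rng, n=12, d=3)
        C = tukey_contrast(3)
        a1 = ats1(eff.p_hat, V, C, ds.n_subjects)
        big_n = 10_000
        p_f = stats.f.sf(a1.statistic / a1.df1, a1.df1, (big_n - 1) * a1.df1)
        assert p_f == pytest.approx(a1.p_value, abs=5e-4)

    def test_moment_match_under_null(self):
        """E[A_n] under the null is close to its Box-matched df."""
        rng = np.random.default_rng(5)
        cfg = ScenarioConfig(d=3, n=50, sigma="sigma1", missing_mechanism="none",
                             reps=0, seed=13)
        C = tukey_contrast(3)
        stats_, dfs = [], []
        for rep in range(400):
            from nparrm.simulation import generate
            ds = generate(cfg, rep)
            eff = unweighted_effects(ds)
            V = covariance_psd(ds, eff)
            r = ats1(eff.p_hat, V, C, ds.n_subjects)
            stats_.append(r.statistic)
            dfs.append(r.df1)
        se = np.std(stats_) / np.sqrt(len(stats_))
        assert abs(np.mean(stats_) - np.mean(dfs)) < 3 * se + 0.05


class TestEquicoordinateQuantile:
    def test_single_statistic_normal(self):
        assert equicoordinate_quantile(np.eye(1), 0.05) == pytest.approx(
            stats.norm.ppf(0.975), abs=1e-3)

    def test_single_statistic_t(self):
        assert equicoordinate_quantile(np.eye(1), 0.05, df=10) == pytest.approx(
            stats.t.ppf(0.975, 10), abs=1e-3)

    def test_independent_pair_factorizes(self):
        expected = stats.norm.ppf((1 + np.sqrt(0.95)) / 2)
        assert equicoordinate_quantile(np.eye(2), 0.05) == pytest.approx(
            expected, abs=1e-3)

    def test_perfect_correlation_degenerates_to_univariate(self):
        R = np.ones((2, 2))
        z = equicoordinate_quantile(R, 0.05)
        assert z == pytest.approx(stats.norm.ppf(0.975), abs=2e-3)

    def test_t_quantile_exceeds_normal_quantile(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert (equicoordinate_quantile(R, 0.05, df=9)
                > equicoordinate_quantile(R, 0.05))

    def test_invalid_inputs(self):
        from nparrm import ValidationError
        with pytest.raises(ValidationError):
            equicoordinate_quantile(np.eye(2), 1.5)
        with pytest.raises(ValidationError):
            equicoordinate_quantile(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.05)


class TestMCTP:
    def test_single_contrast_matches_t_pvalue(self, rng):
        """With q = 1 there is no multiplicity: the adjusted p-value is the
        two-sided t_{n-1} p-value of the single statistic."""
        ds = random_missing_dataset(rng, n=14, d=2, integer=False,
                                    missing_prob=0.15)
        res = mctp(ds, ContrastSpec(np.array([[-1.0, 1.0]])), approx="mvt")
        expected = 2 * stats.t.sf(abs(res.T[0]), ds.n_subjects - 1)
        assert res.p_adjusted[0] == pytest.approx(expected, abs=2e-3)
        assert res.global_T0 == pytest.approx(abs(res.T[0]))

    def test_compatibility_of_intervals_and_pvalues(self, rng):
        """Single-step adjusted p-values and the simultaneous intervals are
        compatible: p <= alpha iff the interval excludes zero (away from the
        solver tolerance boundary)."""
        for _ in range(8):
            ds = random_missing_dataset(rng, n=15, d=3, integer=False,
                                        missing_prob=0.15)
            res = mctp(ds, tukey_contrast(3), alpha=0.05)
            for l in range(len(res.T)):
                if abs(res.p_adjusted[l] - res.alpha) < 2e-3:
                    continue  # within quantile-solver tolerance of the boundary
                excludes = res.sci_lower[l] > 0 or res.sci_upper[l] < 0
                assert (res.p_adjusted[l] <= res.alpha) == excludes

    def test_global_decision_consistency(self, rng):
        ds = random_missing_dataset(rng, n=15, d=3, integer=False)
        res = mctp(ds, tukey_contrast(3), alpha=0.05)
        assert res.reject_global == (np.nanmin(res.p_adjusted) <= res.alpha
                                     or res.p_global <= res.alpha)
        assert res.p_global == pytest.approx(np.nanmin(res.p_adjusted), abs=1e-9)

    def test_correlation_matrix_valid(self, rng):
        ds = random_missing_dataset(rng, n=15, d=4, integer=False)
        res = mctp(ds, tukey_contrast(4))
        R = res.R_hat
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-10)
        assert np.nanmax(np.abs(R)) <= 1 + 1e-10
        np.testing.assert_allclose(R, R.T, atol=1e-10)

    def test_mvt_quantile_at_least_mvn_quantile(self, rng):
        ds = random_missing_dataset(rng, n=12, d=3, integer=False)
        C = tukey_contrast(3)
        assert mctp(ds, C, approx="mvt").quantile >= mctp(ds, C, approx="mvn").quantile

    def test_fast_global_pvalue_matches_full_procedure(self, rng):
        ds = random_missing_dataset(rng, n=15, d=3, integer=False)
        full = mctp(ds, tukey_contrast(3), seed=7)
        fast = mctp_global_pvalue(ds, tukey_contrast(3), seed=7)
        assert fast == pytest.approx(full.p_global, abs=1e-3)

    def test_degenerate_contrast_reported_as_nan(self):
        rngl = np.random.default_rng(2)
        values = rngl.normal(size=(10, 3))
        values[:, 2] = values[:, 1]  # third condition duplicates the second
        ds = RMDataset(values, np.ones((10, 3), dtype=int))
        C = ContrastSpec(np.array([[0.0, -1.0, 1.0], [-1.0, 1.0, 0.0]]))
        with pytest.warns(RuntimeWarning):
            res = mctp(ds, C)
        assert np.isnan(res.T[0]) and np.isfinite(res.T[1])


def test_all_methods_invariant_under_monotone_transforms(rng):
    """WTS, both ATS versions and the comparator tests for the
    distribution-level hypothesis give identical p-values after a strictly
    increasing transformation of all values."""
    ds = random_missing_dataset(rng, n=12, d=3, integer=False, missing_prob=0.15)
    obs = ds.lam == 1
    tds = RMDataset(np.where(obs, np.exp(ds.values), np.nan), ds.lam)
    C = tukey_contrast(3)
    for a, b in [(ds, tds)]:
        ea, eb = unweighted_effects(a), unweighted_effects(b)
        Va, Vb = covariance_psd(a, ea), covariance_psd(b, eb)
        for fn in (wts, ats1, ats2):
            assert fn(ea.p_hat, Va, C, a.n_subjects).p_value == pytest.approx(
                fn(eb.p_hat, Vb, C, b.n_subjects).p_value, abs=1e-10)
        assert wts_weighted(a, C).p_value == pytest.approx(
            wts_weighted(b, C).p_value, abs=1e-10)
        assert ats_weighted(a, C).p_value == pytest.approx(
            ats_weighted(b, C).p_value, abs=1e-10)
        assert mctp(a, C, seed=3).p_global == pytest.approx(
            mctp(b, C, seed=3).p_global, abs=1e-3)


def test_level_under_heteroscedastic_null():
    """Under a heteroscedastic null in the relative effects (unequal
    variances, common center) ATS(2) and the MCTP hold the 5% level within
    the 2,000-replicate binomial band at n = 50."""
    cfg = ScenarioConfig(d=3, n=50, sigma="sigma3", missing_mechanism="mcar",
                         missing_rate=0.1, reps=2000, alpha=0.05, seed=2024)
    res = run_study(cfg, ["ats2", "mctp"])
    for method in ("ats2", "mctp"):
        assert res.failures[method] == 0
        assert 0.035 <= res.rejection_rate[method] <= 0.065, (
            f"{method}: {res.rejection_rate[method]}")
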