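"""Hinge (bi-segmental) regression: exactness, equivariance, oracle checks."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from critweight import BisegmentalRegression, StarvationRecord, \
    fit_bisegmental, profile_rss
from critweight.bisegmental import _valid_mask, default_grid
from critweight.exceptions import DegenerateFitWarning, InvariantError, \
    NoBreakpointError


def dense_grid_oracle(x, y, tol=0.01):
    """Independent exhaustive minimizer: full-design lstsq at every tau on a
    dense grid over the valid region."""
    distinct = np.unique(x)
    lo, hi = distinct[1], distinct[-2]
    taus = lo + tol * np.arange(int(np.floor((hi - lo) / tol + 1e-9)) + 1)
    taus = taus[_valid_mask(distinct, taus)]
    best_rss, best_tau = np.inf, None
    for t in taus:
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        if rss < best_rss - 1e-12:
            best_rss, best_tau = rss, float(t)
    return best_tau, best_rss


class TestExactRecovery:
    def test_noise_free_piecewise(self, exact_piecewise_records):
        fit = fit_bisegmental(exact_piecewise_records)
        assert fit.tau == pytest.approx(8.0, abs=0.01)
        assert fit.beta1 == pytest.approx(-2.0, abs=1e-6)
        assert fit.post_slope == pytest.approx(0.0, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-6)

    def test_translation_equivariance(self, exact_piecewise_records):
        shifted = [
            StarvationRecord(r.larva_id, r.group, r.age_at_starvation,
                             r.time_to_pupariation + 10.0)
            for r in exact_piecewise_records
        ]
        f0 = fit_bisegmental(exact_piecewise_records)
        f1 = fit_bisegmental(shifted)
        assert f1.tau == pytest.approx(f0.tau, abs=1e-9)
        assert f1.beta1 == pytest.approx(f0.beta1, abs=1e-6)
        assert f1.beta0 == pytest.approx(f0.beta0 + 10.0, abs=1e-6)

    def test_age_scaling_equivariance(self, exact_piecewise_records):
        k = 2.0
        scaled = [
            StarvationRecord(r.larva_id, r.group, k * r.age_at_starvation,
                             r.time_to_pupariation)
            for r in exact_piecewise_records
        ]
        f0 = fit_bisegmental(exact_piecewise_records)
        f1 = fit_bisegmental(scaled)
        assert f1.tau == pytest.approx(k * f0.tau, abs=0.02)
        assert f1.beta1 == pytest.approx(f0.beta1 / k, abs=1e-6)


class TestNoisyRecovery:
    def test_recovers_true_breakpoint_and_matches_dense_oracle(self):
        """500 larvae, true hinge at 9 hr: tau within 1 hr of truth and equal
        to the exhaustive dense-grid minimizer on the same draw."""
        rng = np.random.default_rng(7)
        ages = np.repeat(np.arange(0, 26, 2.0), 39)[:500]
        y = 50.0 - 1.5 * ages + 1.5 * np.maximum(0.0, ages - 9.0) \
            + rng.normal(0, 2, ages.size)
        fit = BisegmentalRegression(ages, y).fit()
        assert abs(fit.tau - 9.0) < 1.0
        oracle_tau, oracle_rss = dense_grid_oracle(ages, y)
        assert fit.tau == pytest.approx(oracle_tau, abs=0.011)
        assert fit.rss == pytest.approx(oracle_rss, rel=1e-6)

    def test_estimation_error_shrinks_with_sample_size(self):
        """Median |tau_hat - tau*| over 200 seeds decreases from n=52 to n=494."""
        errs = {4: [], 38: []}
        for n_per_age in errs:
            for s in range(200):
                rng = np.random.default_rng(100_000 + s)
                ages = np.repeat(np.arange(0, 26, 2.0), n_per_age)
                y = 50.0 - 1.5 * ages + 1.5 * np.maximum(0.0, ages - 9.0) \
                    + rng.normal(0, 2, ages.size)
                errs[n_per_age].append(
                    abs(BisegmentalRegression(ages, y).fit().tau - 9.0))
        assert np.median(errs[38]) < np.median(errs[4])


class TestProfile:
    def test_exact_data_profile_has_unique_zero(self, exact_piecewise_records):
        prof = profile_rss(exact_piecewise_records, [4.0, 6.0, 8.0, 10.0, 12.0])
        rss = dict(prof)
        assert rss[8.0] == pytest.approx(0.0, abs=1e-6)
        assert all(v > 1e-3 for t, v in rss.items() if t != 8.0)

    def test_profile_minimum_equals_fit_rss(self, wt_cohort):
        fit = fit_bisegmental(wt_cohort)
        prof = profile_rss(wt_cohort, fit.grid)
        assert fit.rss <= min(r for _, r in prof) + 1e-9

    def test_grid_optimality(self, wt_cohort):
        """RSS at the refined tau is no worse than at any coarse candidate."""
        fit = fit_bisegmental(wt_cohort)
        for _, rss in profile_rss(wt_cohort, fit.grid):
            assert fit.rss <= rss + 1e-9

    def test_constant_response_flat_profile_warns_and_takes_smallest(self):
        recs = [StarvationRecord(f"L{i}", "wt", float(a), 30.0)
                for i, a in enumerate(np.repeat(np.arange(0, 22, 2.0), 2))]
        with pytest.warns(DegenerateFitWarning):
            fit = fit_bisegmental(recs)
        assert fit.tau == pytest.approx(default_grid(
            np.repeat(np.arange(0, 22, 2.0), 2))[0])


class TestPreconditionsAndModes:
    def test_too_few_records(self):
        recs = [StarvationRecord(f"L{i}", "wt", float(2 * i), 40.0 - i)
                for i in range(5)]
        with pytest.raises(InvariantError):
            fit_bisegmental(recs)

    def test_too_few_distinct_ages(self):
        recs = [StarvationRecord(f"L{i}", "wt", float(i % 3), 40.0 + 0.1 * i)
                for i in range(9)]
        with pytest.raises(NoBreakpointError):
            fit_bisegmental(recs)

    def test_nonpupariated_records_excluded_and_counted(self,
                                                       exact_piecewise_records):
        recs = exact_piecewise_records + [
            StarvationRecord("dead", "wt", 4.0, 1.0, pupariated=False)]
        fit = fit_bisegmental(recs)
        assert fit.n == len(exact_piecewise_records)
        assert fit.n_excluded == 1

    def test_disjoint_mode_on_exact_data(self, exact_piecewise_records):
        fit = fit_bisegmental(exact_piecewise_records, continuous=False)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(-2.0, abs=1e-9)
        assert fit.post_slope == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, wt_cohort):
        f1 = fit_bisegmental(wt_cohort)
        f2 = fit_bisegmental(wt_cohort)
        assert f1.tau == f2.tau and f1.rss == f2.rss

    def test_predict_matches_segments(self, exact_piecewise_records):
        fit = fit_bisegmental(exact_piecewise_records)
        assert fit.predict(4.0) == pytest.approx(42.0, abs=1e-5)
        assert fit.predict(16.0) == pytest.approx(34.0, abs=1e-5)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(shift=st.floats(-20, 20), seed=st.integers(0, 10_000))
def test_translation_equivariance_property(shift, seed):
    rng = np.random.default_rng(seed)
    ages = np.repeat(np.arange(0, 22, 2.0), 3)
    y = 45.0 - 1.2 * ages + 1.2 * np.maximum(0.0, ages - 10.0) \
        + rng.normal(0, 1.5, ages.size)
    f0 = BisegmentalRegression(ages, y).fit()
    f1 = BisegmentalRegression(ages, y + shift).fit()
    assert f1.tau == pytest.approx(f0.tau, abs=1e-9)
    assert f1.beta0 == pytest.approx(f0.beta0 + shift, abs=1e-6)
    assert f1.beta1 == pytest.approx(f0.beta1, abs=1e-8)
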