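"""COV grading, transfer metrics, paired and single-case t-tests,
correlations, and the kinematics-histology regressions."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from headkin import (
    KinematicSummary,
    cohort_table,
    cov,
    grade_cov,
    kinematics_pathology_regression,
    one_vs_many_t,
    paired_t,
    pearson,
    percent_change,
    percent_transfer,
    round_half_up,
)
from headkin.errors import (
    DegenerateGroupError,
    InsufficientDataError,
    UndefinedStatError,
)
from headkin.repro_stats import one_vs_many_t_vectorized

from oracles import students_t_two_sided_p


def sample_with(mean, sd, n, seed=0):
    """Exact-moment sample: standardized noise rescaled to (mean, sd)."""
    z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestCov:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(250.68, 2.88, 1.1), (129.09, 11.49, 8.9), (127.36, 10.91, 8.6),
         (6.45, 0.05, 0.8), (4.42, 1.03, 23.3)],
    )
    def test_tabulated_pairs(self, mean, sd, expected):
        assert round_half_up(cov(mean, sd), 1) == expected

    def test_zero_dispersion(self):
        assert cov(42.0, 0.0) == 0.0

    def test_raw_sample_input(self):
        s = sample_with(129.09, 11.49, 9)
        assert cov(s) == pytest.approx(100 * 11.49 / 129.09, rel=1e-9)

    def test_nonpositive_mean_undefined(self):
        with pytest.raises(UndefinedStatError):
            cov(0.0, 1.0)
        with pytest.raises(UndefinedStatError):
            cov(-3.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(c=st.floats(0.1, 1000.0), seed=st.integers(0, 100))
    def test_scale_invariance(self, c, seed):
        s = np.abs(np.random.default_rng(seed).normal(50, 5, 8)) + 1.0
        assert cov(c * s) == pytest.approx(cov(s), rel=1e-9)


class TestGradeCov:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.1, "good"), (4.99, "good"), (5.0, "acceptable"), (8.9, "acceptable"),
         (10.0, "acceptable"), (10.01, "marginal"), (20.0, "marginal"),
         (21.0, "poor")],
    )
    def test_bands(self, value, expected):
        assert grade_cov(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(Exception):
            grade_cov(-1.0)

    def test_monotone(self):
        order = {"good": 0, "acceptable": 1, "marginal": 2, "poor": 3}
        grid = np.linspace(0, 40, 401)
        ranks = [order[grade_cov(v)] for v in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestTransferMetrics:
    def test_headline_transfer(self):
        assert round_half_up(percent_transfer(129.09, 250.68), 0) == 51
    def test_headline_duration_change(self):
        assert round_half_up(percent_change(11.1, 5.82), 0) == 91

    def test_identity(self):
        assert percent_transfer(7.0, 7.0) == 100.0

    def test_zero_denominator(self):
        with pytest.raises(UndefinedStatError):
            percent_transfer(1.0, 0.0)


class TestPairedT:
    def test_null_case(self):
        x = np.arange(9, dtype=float)
        res = paired_t(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_reconstructed_headline_t(self):
        """A difference sample with mean 121.59 and SD 12.579 over n=9 gives
        t = mean/(sd/sqrt(n)) = 29.00 on 8 df."""
        d = sample_with(121.59, 12.579, 9, seed=1)
        y = sample_with(250.68, 2.88, 9, seed=2)
        res = paired_t(y + d, y)
        assert res.t == pytest.approx(29.00, abs=0.005)
        assert res.df == 8
        assert res.p < 0.001

    def test_matches_scipy(self, rng):
        x = rng.normal(10, 2, 12)
        y = rng.normal(9, 2, 12)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_p_against_independent_cdf(self):
        """|t| = 2.306 at df = 8 is the two-sided 5% quantile; p computed via
        the incomplete-beta route must agree."""
        d = sample_with(2.306 / np.sqrt(9), 1.0, 9, seed=3)
        res = paired_t(d, np.zeros(9))
        assert res.t == pytest.approx(2.306, abs=1e-9)
        assert res.p == pytest.approx(students_t_two_sided_p(2.306, 8), rel=1e-9)
        assert res.p == pytest.approx(0.05, abs=5e-4)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert a.t == pytest.approx(-b.t, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            paired_t([1.0], [2.0])


class TestOneVsManyT:
    def test_at_group_mean(self):
        g = sample_with(129.09, 11.49, 9)
        res = one_vs_many_t(float(np.mean(g)), g)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_example(self):
        # replication animal at 132.78 vs the initial cohort summary
        g = sample_with(129.09, 11.49, 9, seed=4)
        res = one_vs_many_t(132.78, g)
        expected_t = (132.78 - 129.09) / (11.49 * np.sqrt(1 + 1 / 9))
        assert res.t == pytest.approx(expected_t, abs=1e-6)
        assert res.t == pytest.approx(0.3046, abs=5e-4)
        assert res.df == 8
        assert res.p == pytest.approx(0.77, abs=0.01)

    def test_degenerate_group(self):
        with pytest.raises(DegenerateGroupError):
            one_vs_many_t(1.0, np.full(9, 5.0))

    def test_type_one_error_calibration(self):
        """Single cases drawn from the control population should reject at
        ~alpha; quick 2000-sim check (the 10k sweep runs in acceptance)."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            g = rng.normal(129.0, 11.5, 9)
            x = rng.normal(129.0, 11.5)
            if one_vs_many_t(x, g).p < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_sim <= 0.075

    def test_vectorized_matches_scalar(self, rng):
        g = rng.normal(10, 2, 9)
        xs = rng.normal(10, 2, 5)
        tv, pv = one_vs_many_t_vectorized(xs, float(np.mean(g)),
                                          float(np.std(g, ddof=1)), 9)
        for x, t_exp, p_exp in zip(xs, tv, pv):
            res = one_vs_many_t(float(x), g)
            assert res.t == pytest.approx(t_exp, rel=1e-12)
            assert res.p == pytest.approx(p_exp, rel=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10, dtype=float)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_r_minus_023_n13_gives_p_045(self):
        """r = -0.23 with n = 13 maps to p = 0.45 through
        t = r sqrt((n-2)/(1-r^2)) on 11 df."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=13)
        z = rng.normal(size=13)
        xs = (x - x.mean()) / x.std()
        zr = z - z.mean() - xs * np.dot(z - z.mean(), xs) / np.dot(xs, xs)
        zr /= zr.std()
        r_target = -0.23
        y = r_target * xs + np.sqrt(1 - r_target**2) * zr
        r, p = pearson(x, y)
        assert r == pytest.approx(-0.23, abs=1e-9)
        t = r * np.sqrt((13 - 2) / (1 - r * r))
        assert p == pytest.approx(students_t_two_sided_p(abs(t), 11), rel=1e-6)
        assert round_half_up(p, 2) == 0.45

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatError):
            pearson(np.ones(5), np.arange(5.0))


class TestRegression:
    def test_exact_linear_combination(self, rng):
        peaks = rng.normal(130, 10, 13)
        fwhms = rng.normal(11, 1.5, 13)
        outcome = 2.0 + 0.5 * peaks - 3.0 * fwhms
        res = kinematics_pathology_regression(peaks, fwhms, outcome)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.df_model == 2 and res.df_resid == 10

    def test_null_p_values_uniform(self):
        """With an outcome independent of the predictors, the omnibus p must
        be uniform on [0,1] (Kolmogorov-Smirnov at 1000 reps)."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(1000):
            peaks = rng.normal(size=10)
            fwhms = rng.normal(size=10)
            outcome = rng.normal(size=10)
            ps.append(kinematics_pathology_regression(peaks, fwhms, outcome).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            kinematics_pathology_regression([1, 2, 3], [4, 5, 6], [7, 8, 9])

    def test_collinear_predictors_warn(self, rng):
        peaks = rng.normal(size=10)
        with pytest.warns(RuntimeWarning, match="collinear"):
            kinematics_pathology_regression(peaks, 2 * peaks, rng.normal(size=10))


def make_summaries(n, peak_mean, peak_sd, sensor="machine", label="e1", seed=0):
    peaks = sample_with(peak_mean, peak_sd, n, seed)
    return [
        KinematicSummary(f"{label}_{i:02d}", sensor, float(p), 5.82, 6.45)
        for i, p in enumerate(peaks)
    ]


class TestCohortTable:
    def test_identical_animals_zero_cov(self):
        s = make_summaries(9, 250.0, 0.0)
        table = cohort_table(s)
        assert (table["cov_pct"] == 0.0).all()
        assert (table["grade"] == "good").all()

    def test_tabulated_cell(self):
        s = make_summaries(9, 250.68, 2.88)
        table = cohort_table(s)
        row = table[table["metric"] == "Peak angular velocity (rad/s)"].iloc[0]
        assert row["mean"] == pytest.approx(250.68)
        assert row["sd"] == pytest.approx(2.88)
        assert row["cov_pct"] == 1.1
        assert row["n"] == 9

    def test_two_experiments_keep_blocks(self):
        s1 = make_summaries(9, 250.68, 2.88, label="e1")
        s2 = make_summaries(4, 250.13, 5.06, label="e2", seed=5)
        by = {x.animal_id: ("exp1" if x.animal_id.startswith("e1") else "exp2")
              for x in s1 + s2}
        table = cohort_table(s1 + s2, by)
        assert set(table["experiment"]) == {"exp1", "exp2"}
        exp2 = table[(table["experiment"] == "exp2")
                     & (table["metric"] == "Peak angular velocity (rad/s)")]
        assert exp2["cov_pct"].iloc[0] == 2.0


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(2.25, 1, 2.3), (2.35, 1, 2.4), (1.1488, 1, 1.1), (8.901, 1, 8.9),
         (90.72, 0, 91.0), (51.496, 0, 51.0), (46.92, 1, 46.9)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
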