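import numpy as np
import pytest
from scipy import stats as sps

from rsikit.errors import ValidationError
from rsikit.survival import (
    _logrank_z,
    cox_univariate,
    km_fit,
    logrank,
    surv_cutpoint,
)


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = km_fit(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km.at_risk, [3, 2, 1])

    def test_all_censored_curve_is_flat(self):
        km = km_fit(np.array([1.0, 2.0, 5.0]), np.array([0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_mixed_records_match_hand_computed_table(self):
        # t: 1(e) 2(c) 3(e) 3(e) 4(c) 5(e)
        # S(1)=5/6; S(3)=5/6*(1-2/4)=5/12; S(5)=5/12*(1-1/1)=0
        time = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        km = km_fit(time, event)
        surv = dict(zip(km.times, km.survival))
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[3.0] == pytest.approx(5 / 12)
        assert surv[5.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(71)
        t = rng.exponential(2.0, 50)
        km = km_fit(t, np.ones(50, int))
        for q in (0.5, 1.0, 2.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_fit(np.array([-1.0]), np.array([1]))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        chi2, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(73)
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = rng.integers(0, 2, 60)
        assert logrank(t, e, g) == pytest.approx(logrank(t, e, 1 - g))

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(79)
        t = rng.exponential(1, 60)
        e = np.ones(60, int)
        ps = []
        for _ in range(500):
            g = rng.permutation(np.repeat([0, 1], 30))
            z = _logrank_z(t, e, g == 1)
            ps.append(2 * sps.norm.sf(abs(z)))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(83)
        t = np.r_[rng.exponential(1.0, 200), rng.exponential(0.25, 200)]
        e = np.ones(400, int)
        g = np.repeat(["slow", "fast"], 200)
        _, p = logrank(t, e, g)
        assert p < 1e-6

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank(np.array([1.0, 2.0]), np.array([0, 0]), np.array([0, 1]))


class TestCox:
    def test_null_coverage(self):
        rng = np.random.default_rng(89)
        covered = 0
        for _ in range(50):
            t = rng.exponential(1.0, 500)
            e = (rng.uniform(size=500) < 0.8).astype(int)
            x = rng.normal(size=500)
            est = cox_univariate(t, e, x)
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered >= 45

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, 500)
        lam = 0.1 * np.where(g == 1, 2.0, 1.0)
        te = rng.exponential(1 / lam)
        tc = rng.exponential(1 / 0.05, 500)
        est = cox_univariate(np.minimum(te, tc), (te <= tc).astype(int),
                             g.astype(float))
        assert 1.6 <= est.hr <= 2.5
        assert est.ci_low <= est.hr <= est.ci_high

    def test_covariate_scaling_rescales_log_hr(self):
        rng = np.random.default_rng(97)
        t = rng.exponential(1.0, 300)
        e = np.ones(300, int)
        x = rng.normal(size=300) + 0.3 * np.log(t + 0.1)
        a = cox_univariate(t, e, x)
        b = cox_univariate(t, e, 10 * x)
        assert b.log_hr == pytest.approx(a.log_hr / 10, rel=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_univariate(np.array([1.0, 2.0]), np.array([1, 1]),
                           np.array([1.0, 1.0]))


class TestSurvCutpoint:
    def test_recovers_planted_change_point(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(0, 1, 600)
        lam = 0.1 * np.where(s < 0.46, 3.0, 1.0)
        te = rng.exponential(1 / lam)
        tc = rng.exponential(1 / 0.05, 600)
        cp = surv_cutpoint(np.minimum(te, tc), (te <= tc).astype(int), s)
        assert cp.value == pytest.approx(0.46, abs=0.05)
        assert cp.n_low >= 60 and cp.n_high >= 60

    def test_null_scores_not_significant_on_independent_replicate(self):
        rng = np.random.default_rng(101)
        hits = 0
        runs = 100
        for _ in range(runs):
            t = rng.exponential(1.0, 200)
            e = np.ones(200, int)
            s = rng.uniform(size=200)
            cp = surv_cutpoint(t, e, s)
            # apply the selected cutpoint to an independent replicate
            t2 = rng.exponential(1.0, 200)
            s2 = rng.uniform(size=200)
            _, p = logrank(t2, np.ones(200, int),
                           (s2 > cp.value).astype(int))
            hits += p < 0.05
        assert hits <= 0.1 * runs  # not significant in >= 90% of runs

    def test_minprop_half_forces_median_split(self):
        rng = np.random.default_rng(103)
        s = rng.uniform(size=100)
        t = rng.exponential(1.0, 100)
        cp = surv_cutpoint(t, np.ones(100, int), s, minprop=0.5)
        assert cp.n_low == cp.n_high == 50
        order = np.sort(s)
        assert cp.value == pytest.approx((order[49] + order[50]) / 2)

    def test_inadmissible_split_errors(self):
        s = np.r_[np.zeros(99), 1.0]  # any split isolates one sample
        t = np.arange(1.0, 101.0)
        with pytest.raises(ValidationError):
            surv_cutpoint(t, np.ones(100, int), s, minprop=0.4)
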