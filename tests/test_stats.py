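from fractions import Fraction
from math import comb

import numpy as np
import pytest

from cinwgs.stats import (
    SurvivalRecord,
    chisq_test,
    cox_fit,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    prop_trend_test,
)
from cinwgs.synthetic import cohort_records, simulate_cohort


def enumerate_fisher(table):
    """Exact rational enumeration over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestFisher:
    def test_cohort_association_value(self):
        # TP53 loss x CIN category from the 32-case cohort
        p = fisher_exact_2x2([[12, 2], [3, 15]])
        assert round(p, 5) == 0.00021

    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_matches_rational_enumeration(self, rng):
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            p = fisher_exact_2x2(t)
            assert p == pytest.approx(enumerate_fisher(t.tolist()), abs=1e-9)

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(1, 12, size=(2, 2))
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestChisq:
    def test_expected_table_gives_zero(self):
        stat, p, df = chisq_test([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        stat, p, df = chisq_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 3)).astype(float)
            stat, _, df = chisq_test(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            oracle = float(((t - expected) ** 2 / expected).sum())
            assert stat == pytest.approx(oracle, rel=1e-12)
            assert df == 2


class TestPropTrend:
    def test_equal_proportions_near_zero(self):
        z, p = prop_trend_test([10, 20, 30], [100, 200, 300])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_increasing_proportions_significant(self):
        z, p = prop_trend_test([40, 80, 120], [200, 200, 200])
        assert p < 0.05
        assert z > 0

    def test_reversal_flips_sign(self):
        x, n = [5, 10, 20], [50, 50, 50]
        z1, p1 = prop_trend_test(x, n, scores=[-1, 0, 1])
        z2, p2 = prop_trend_test(x[::-1], n[::-1], scores=[-1, 0, 1])
        assert z2 == pytest.approx(-z1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            prop_trend_test([5, 60], [10, 50])


class TestKaplanMeier:
    def test_all_censored(self):
        recs = [SurvivalRecord(f"s{i}", t, False) for i, t in enumerate([1, 2, 3])]
        km = km_estimate(recs)
        assert len(km.times) == 0
        assert np.all(km.survival_at([0.5, 5.0]) == 1.0)

    def test_two_events_hand_computation(self):
        recs = [SurvivalRecord("a", 1.0, True), SurvivalRecord("b", 2.0, True)]
        km = km_estimate(recs)
        assert list(km.times) == [1.0, 2.0]
        assert km.survival == pytest.approx([0.5, 0.0])
        assert km.survival_at(0.5) == pytest.approx(1.0)
        assert km.survival_at(1.5) == pytest.approx(0.5)

    def test_matches_exponential_truth(self):
        rng = np.random.default_rng(42)
        lam = 0.05
        t = rng.exponential(1 / lam, size=500)
        recs = [SurvivalRecord(f"s{i}", ti, True) for i, ti in enumerate(t)]
        km = km_estimate(recs)
        truth = np.exp(-lam * km.times)
        assert np.max(np.abs(km.survival - truth)) < 0.06

    def test_greenwood_variance_nonnegative_monotone_risk(self):
        rng = np.random.default_rng(7)
        recs = [
            SurvivalRecord(f"s{i}", float(t), bool(e))
            for i, (t, e) in enumerate(
                zip(rng.exponential(10, 50), rng.random(50) < 0.7)
            )
        ]
        km = km_estimate(recs)
        assert (km.variance >= 0).all()
        assert (np.diff(km.n_at_risk) <= 0).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("s", 0.0, True)


class TestLogrank:
    def test_identical_groups(self):
        recs = [SurvivalRecord(f"s{i}", float(i + 1), True) for i in range(10)]
        stat, p, df = logrank_test({"a": recs, "b": list(recs)})
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        g1 = [SurvivalRecord(f"a{i}", float(t), True) for i, t in enumerate(rng.exponential(10, 30))]
        g2 = [SurvivalRecord(f"b{i}", float(t), True) for i, t in enumerate(rng.exponential(20, 30))]
        s1, p1, _ = logrank_test({"a": g1, "b": g2})
        s2, p2, _ = logrank_test({"b": g2, "a": g1})
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_power_under_large_hazard_ratio(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            g1 = [SurvivalRecord(f"a{i}", float(t), True)
                  for i, t in enumerate(rng.exponential(1 / 0.12, 200))]
            g2 = [SurvivalRecord(f"b{i}", float(t), True)
                  for i, t in enumerate(rng.exponential(1 / 0.02, 200))]
            _, p, _ = logrank_test({"hi": g1, "lo": g2})
            wins += p < 0.001
        assert wins >= 19  # >= 95%

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test({"only": [SurvivalRecord("s", 1.0, True)]})


class TestCox:
    def test_identical_event_patterns_hr_near_one(self):
        recs = []
        for g in (0.0, 1.0):
            for i, t in enumerate([2.0, 4.0, 6.0, 8.0, 10.0]):
                recs.append(
                    SurvivalRecord(f"g{g}-{i}", t, True, {"x": g})
                )
        res = cox_fit(recs, ["x"])
        assert res.hazard_ratios["x"] == pytest.approx(1.0, abs=0.05)

    def test_parameter_recovery_large_n(self):
        true_log_hr = 1.5
        estimates = []
        for rep in range(20):
            df = simulate_cohort(
                n=1000, hr_high=np.exp(true_log_hr), p_high=0.5,
                censor_rate=0.005, seed=600 + rep,
            )
            res = cox_fit(cohort_records(df), ["cin_high"])
            estimates.append(res.log_hr["cin_high"])
        assert np.mean(estimates) == pytest.approx(true_log_hr, abs=0.15)

    def test_small_sample_ci_coverage(self):
        true_log_hr = np.log(6.0)
        covered = 0
        n_reps = 50
        for rep in range(n_reps):
            df = simulate_cohort(
                n=32, hr_high=6.0, p_high=14 / 32, censor_rate=0.01,
                seed=700 + rep,
            )
            if df.cin_category.nunique() < 2 or df.event.sum() == 0:
                covered += 1  # unidentifiable draw; exclude conservatively
                continue
            res = cox_fit(cohort_records(df), ["cin_high"])
            lo = np.log(res.ci_lower["cin_high"])
            hi = np.log(res.ci_upper["cin_high"])
            covered += lo <= true_log_hr <= hi
        assert covered / n_reps >= 0.9

    def test_reciprocal_identity_on_relabeling(self):
        df = simulate_cohort(n=200, hr_high=3.0, p_high=0.5, seed=4)
        recs = cohort_records(df)
        flipped = [
            SurvivalRecord(r.sample_id, r.time, r.event,
                           {"cin_high": 1.0 - r.covariates["cin_high"]})
            for r in recs
        ]
        hr = cox_fit(recs, ["cin_high"]).hazard_ratios["cin_high"]
        hr_flip = cox_fit(flipped, ["cin_high"]).hazard_ratios["cin_high"]
        assert hr_flip == pytest.approx(1.0 / hr, rel=1e-6)

    def test_no_events_rejected(self):
        recs = [SurvivalRecord("a", 1.0, False, {"x": 0.0}),
                SurvivalRecord("b", 2.0, False, {"x": 1.0})]
        with pytest.raises(ValueError):
            cox_fit(recs, ["x"])

    def test_zero_variance_covariate_rejected(self):
        recs = [SurvivalRecord("a", 1.0, True, {"x": 1.0}),
                SurvivalRecord("b", 2.0, True, {"x": 1.0})]
        with pytest.raises(ValueError):
            cox_fit(recs, ["x"])
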