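import numpy as np
import pytest
from scipy import stats as sps

from fusionsieve.quant_survival import (CtRecord, SurvivalRecord, ddct,
                                        km_estimate, logrank_test, rank_sum_test)

from oracles import km_by_hand, logrank_by_risk_table


def ct(sid, target, ref=20.0, group="mCRC"):
    return CtRecord(sample_id=sid, target_ct=target, reference_ct=ref, group=group)


class TestDdct:
    def test_two_cycle_difference_gives_fourfold(self):
        recs = [ct("case", 24.0), ct("calib", 26.0, group="pCRC")]
        rel = {r.sample_id: r for r in ddct(recs, calibrator="calib")}
        assert rel["case"].ddct == pytest.approx(-2.0)
        assert rel["case"].rq == pytest.approx(4.0)

    def test_calibrator_sample_rq_is_exactly_one(self):
        recs = [ct("a", 24.0), ct("b", 27.5, ref=19.0), ct("c", 22.0, ref=21.0)]
        for calib in ("a", "b", "c"):
            rel = {r.sample_id: r for r in ddct(recs, calibrator=calib)}
            assert rel[calib].rq == 1.0

    def test_group_mean_calibrator(self):
        recs = [ct("m1", 23.0), ct("p1", 25.0, group="pCRC"), ct("p2", 27.0, group="pCRC")]
        rel = {r.sample_id: r for r in ddct(recs, calibrator="pCRC")}
        # pCRC mean dCt = 6; mCRC dCt = 3 -> RQ = 2^3
        assert rel["m1"].rq == pytest.approx(8.0)

    def test_rq_monotone_decreasing_in_target_ct(self):
        grid = np.linspace(18, 30, 25)
        recs = [ct(f"s{i}", float(t)) for i, t in enumerate(grid)] + \
               [ct("cal", 24.0, group="pCRC")]
        rel = ddct(recs, calibrator="cal")
        rqs = [r.rq for r in rel[:-1]]
        assert all(a > b for a, b in zip(rqs, rqs[1:]))

    def test_unresolvable_calibrator(self):
        with pytest.raises(ValueError, match="calibrator"):
            ddct([ct("a", 24.0)], calibrator="nope")


class TestRankSum:
    def test_exact_enumeration_small_example(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)  # 2 * P(U <= 0) = 2/6, by enumeration

    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = rank_sum_test([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_matches_scipy_exact_on_random_small_samples(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            u, p = rank_sum_test(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_asymptotic_on_larger_samples(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = rng.normal(0.5, size=18)
        u, p = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


def srec(t, e=1, pos=False, sid=None):
    return SurvivalRecord(sample_id=sid or f"s{t}-{pos}", time=t, event=e,
                          fusion_positive=pos)


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0]
        km = km_estimate([srec(t, sid=f"x{i}") for i, t in enumerate(times)])
        for t in (1.0, 3.0, 4.0, 5.0):
            assert km.at(t) == pytest.approx(1 - np.mean(np.array(times) <= t))

    def test_all_censored_flat_at_one(self):
        km = km_estimate([srec(t, e=0, sid=f"c{t}") for t in (2.0, 5.0, 9.0)])
        assert km.times.size == 0 and km.at(100.0) == 1.0

    def test_hand_worked_censored_example(self):
        # deaths at 5 and 15, censored at 10: S(5)=2/3, S(15)=0
        km = km_estimate([srec(5.0), srec(10.0, e=0, sid="c"), srec(15.0, sid="z")])
        assert km.at(5.0) == pytest.approx(2 / 3)
        assert km.at(15.0) == pytest.approx(0.0)

    def test_record_order_invariance_and_late_censoring(self):
        recs = [srec(2.0), srec(7.0, sid="b"), srec(4.0, e=0, sid="c")]
        km1 = km_estimate(recs)
        km2 = km_estimate(recs[::-1])
        assert np.array_equal(km1.times, km2.times)
        assert np.array_equal(km1.survival, km2.survival)
        # a censoring after the last event adds no step time and the curve
        # still ends strictly positive (nobody new can die)
        km3 = km_estimate(recs + [srec(99.0, e=0, sid="late")])
        assert np.array_equal(km3.times, km1.times)
        assert km3.survival[-1] > 0

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(8)
        recs = [srec(float(t), e=int(e), sid=f"r{i}")
                for i, (t, e) in enumerate(zip(rng.exponential(10, 30),
                                               rng.integers(0, 2, 30)))]
        if not any(r.event for r in recs):
            recs[0] = srec(1.0, e=1, sid="force")
        km = km_estimate(recs)
        hand = km_by_hand([r.time for r in recs], [r.event for r in recs])
        assert [(t, pytest.approx(s)) for t, s in
                zip(km.times, km.survival)] == hand

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        t = rng.exponential(12, 40)
        e = rng.integers(0, 2, 40)
        km = km_estimate([srec(float(ti), e=int(ei), sid=f"l{i}")
                          for i, (ti, ei) in enumerate(zip(t, e))])
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]))


class TestLogrank:
    def test_identical_strata_give_null_result(self):
        recs = [srec(t, pos=p, sid=f"{t}{p}") for t in (1.0, 2.0, 3.0)
                for p in (True, False)]
        res = logrank_test(recs)
        assert res.chi_square == pytest.approx(0.0) and res.p_value == 1.0

    def test_no_events_gives_p_one(self):
        recs = [srec(5.0, e=0, pos=True), srec(6.0, e=0, pos=False)]
        res = logrank_test(recs)
        assert (res.chi_square, res.p_value) == (0.0, 1.0)

    def test_four_patient_worked_example_matches_risk_table(self):
        # arm A (negative): deaths at 1, 2; arm B (positive): deaths at 3, 4
        recs = [srec(1.0, sid="a1"), srec(2.0, sid="a2"),
                srec(3.0, pos=True, sid="b1"), srec(4.0, pos=True, sid="b2")]
        res = logrank_test(recs)
        expected = logrank_by_risk_table([1, 2, 3, 4], [1, 1, 1, 1],
                                         [False, False, True, True])
        assert res.chi_square == pytest.approx(expected)
        assert res.observed == (2.0, 2.0)

    def test_matches_lifelines_on_random_cohort(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(12)
        recs = [srec(float(t), e=int(e), pos=bool(g), sid=f"r{i}")
                for i, (t, e, g) in enumerate(zip(
                    rng.exponential(10, 50), rng.integers(0, 2, 50),
                    rng.integers(0, 2, 50)))]
        res = logrank_test(recs)
        t = np.array([r.time for r in recs])
        e = np.array([r.event for r in recs])
        g = np.array([r.fusion_positive for r in recs])
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert res.chi_square == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            logrank_test([srec(1.0, pos=True)])
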