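"""Kaplan-Meier, log-rank, Cox regression, and cut-point scanning."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pdacsig import (
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    xtile_cutpoint,
)
from pdacsig.survival import miller_siegmund_minp


def records(times, events=None):
    if events is None:
        events = [True] * len(times)
    return [SurvivalRecord(t, e) for t, e in zip(times, events)]


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(records([1, 2, 3, 4]))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(records([3, 7, 9], [False, False, False]))
        assert km.survival_at(100.0) == 1.0
        assert km.median is None

    def test_single_death(self):
        km = km_estimate(records([5]))
        assert km.survival_at(5.0) == 0.0
        assert km.median == 5.0

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 40)
        km = km_estimate(records(t))
        for q in (5.0, 10.0, 20.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord(0.0, True)


class TestLogRank:
    def test_identical_groups_null(self):
        grp = records([1, 3, 5, 8], [True, True, False, True])
        res = logrank_test(grp, list(grp))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        g1 = records(rng.exponential(10, 30))
        g2 = records(rng.exponential(30, 30))
        assert logrank_test(g1, g2).statistic == pytest.approx(
            logrank_test(g2, g1).statistic
        )

    def test_no_events_gives_p_one(self):
        g1 = records([1, 2], [False, False])
        g2 = records([3, 4], [False, False])
        res = logrank_test(g1, g2)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strong_hazard_ratio_detected(self, rng):
        detected = 0
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            g_hi = records(r.exponential(1 / 0.08, 200))
            g_lo = records(r.exponential(1 / 0.02, 200))
            detected += logrank_test(g_hi, g_lo).p_value < 0.001
        assert detected == 10


class TestCox:
    def test_identical_groups_coefficient_zero(self):
        base = [1.0, 3.0, 5.0, 8.0, 13.0, 21.0]
        recs = records(base + base)
        cov = pd.DataFrame({"grp": [0.0] * 6 + [1.0] * 6})
        fit = cox_fit(recs, cov)
        assert abs(fit.summary.loc["grp", "coef"]) < 1e-6
        assert fit.hazard_ratio("grp") == pytest.approx(1.0, abs=1e-5)

    def test_covariate_rescaling_equivariance(self, rng):
        x = rng.standard_normal(80)
        t = rng.exponential(np.exp(-0.8 * x) * 20)
        recs = records(t)
        b1 = cox_fit(recs, pd.DataFrame({"x": x})).summary.loc["x", "coef"]
        b2 = cox_fit(recs, pd.DataFrame({"x": 2.0 * x})).summary.loc["x", "coef"]
        assert b2 == pytest.approx(b1 / 2.0, rel=1e-6)

    def test_agrees_with_lifelines(self, rng):
        x = (rng.random(100) < 0.5).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(1.2 * x)))
        e = rng.random(100) < 0.8
        fit = cox_fit(records(t, e), pd.DataFrame({"x": x}))
        df = pd.DataFrame({"T": t, "E": e.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            float(cph.params_["x"]), rel=1e-4
        )

    def test_breslow_ties_flag(self, rng):
        t = np.repeat([3.0, 6.0, 9.0, 12.0], 10)  # heavy month-resolution ties
        x = rng.standard_normal(40)
        recs = records(t)
        efron = cox_fit(recs, pd.DataFrame({"x": x}), ties="efron")
        breslow = cox_fit(recs, pd.DataFrame({"x": x}), ties="breslow")
        assert efron.ties == "efron" and breslow.ties == "breslow"
        assert efron.summary.loc["x", "coef"] != breslow.summary.loc["x", "coef"]

    def test_missing_covariates_dropped_and_counted(self, rng):
        t = rng.exponential(10, 20)
        x = rng.standard_normal(20)
        cov = pd.DataFrame({"x": x})
        cov.iloc[:3] = np.nan
        fit = cox_fit(records(t), cov)
        assert fit.n_dropped == 3 and fit.n_used == 17

    def test_zero_events_rejected(self):
        recs = records([1.0, 2.0], [False, False])
        with pytest.raises(ValueError, match="events"):
            cox_fit(recs, pd.DataFrame({"x": [0.0, 1.0]}))

    def test_sign_matches_logrank_direction(self, rng):
        hi = rng.exponential(5, 50)
        lo = rng.exponential(50, 50)
        recs = records(np.concatenate([hi, lo]))
        cov = pd.DataFrame({"hi": [1.0] * 50 + [0.0] * 50})
        fit = cox_fit(recs, cov)
        assert fit.summary.loc["hi", "coef"] > 0  # more early deaths -> higher hazard


class TestCutpoint:
    def test_two_distinct_values_reduce_to_plain_logrank(self, rng):
        scores = np.array([0.0] * 10 + [1.0] * 10)
        t = np.concatenate([rng.exponential(50, 10), rng.exponential(5, 10)])
        recs = records(t)
        cut = xtile_cutpoint(scores, recs, min_group=5)
        plain = logrank_test(records(t[:10]), records(t[10:]))
        assert len(cut.scan) == 1
        assert cut.statistic == pytest.approx(plain.statistic, rel=1e-9)
        assert cut.p_corrected == pytest.approx(cut.p_naive)

    def test_scan_matches_direct_logrank_at_every_candidate(self, rng):
        scores = rng.random(40)
        t = rng.exponential(20, 40)
        e = rng.random(40) < 0.7
        recs = records(t, e)
        cut = xtile_cutpoint(scores, recs, min_group=5)
        for cand, stat in zip(cut.scan.candidate, cut.scan.statistic):
            below = [r for r, s in zip(recs, scores) if s < cand]
            above = [r for r, s in zip(recs, scores) if s >= cand]
            assert stat == pytest.approx(
                logrank_test(below, above).statistic, abs=1e-9
            )

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            xtile_cutpoint([1.0] * 10, records(np.arange(1.0, 11.0)))

    def test_min_group_respected(self, rng):
        scores = rng.random(30)
        recs = records(rng.exponential(10, 30))
        cut = xtile_cutpoint(scores, recs, min_group=8)
        assert cut.n_low >= 8 and cut.n_high >= 8

    def test_best_candidate_attains_maximum(self, rng):
        scores = rng.random(30)
        recs = records(rng.exponential(10, 30))
        cut = xtile_cutpoint(scores, recs, min_group=5)
        assert cut.statistic == pytest.approx(cut.scan.statistic.max())


class TestMillerSiegmund:
    def test_corrected_p_bounds(self):
        for p in (1e-6, 1e-3, 0.02, 0.2):
            corrected = miller_siegmund_minp(p, 0.1, 0.9)
            assert p <= corrected <= 1.0

    def test_large_p_saturates(self):
        assert miller_siegmund_minp(0.6, 0.1, 0.9) == 1.0

    def test_monotone_in_p(self):
        ps = [miller_siegmund_minp(p, 0.1, 0.9) for p in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert ps == sorted(ps)
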