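"""Kaplan-Meier, log-rank, Cox screening, forest risk score, tdROC."""

import numpy as np
import pandas as pd
import pytest

from dynrad import (
    SimulationConfig,
    cox_univariate_screen,
    fit_risk_score,
    kaplan_meier,
    logrank_test,
    pfs_pipeline,
    roc_auc,
    simulate_feature_cohort,
    td_roc,
)
from dynrad.survival import SurvivalConfig
from oracles import km_naive, logrank_naive


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # subjects: event at 1, censored at 2, event at 3, censored at 4
        tab = kaplan_meier([1, 2, 3, 4], [1, 0, 1, 0])
        s = dict(zip(tab["time"], tab["survival"]))
        assert s[1.0] == pytest.approx(0.75)
        assert s[3.0] == pytest.approx(0.375)

    def test_equals_empirical_without_censoring(self, rng):
        t = rng.exponential(100, 60)
        tab = kaplan_meier(t, np.ones(60))
        for ti, si in zip(tab["time"], tab["survival"]):
            if ti == 0:
                continue
            assert si == pytest.approx(np.mean(t > ti), abs=1e-12)

    def test_all_censored_is_flat_one(self):
        tab = kaplan_meier([5, 8, 2], [0, 0, 0])
        assert (tab["survival"] == 1.0).all()

    def test_matches_naive_product_limit(self, rng):
        t = np.round(rng.exponential(50, 40), 0) + 1
        e = rng.integers(0, 2, 40)
        if e.sum() == 0:
            e[0] = 1
        tab = kaplan_meier(t, e)
        s = dict(zip(tab["time"], tab["survival"]))
        for ot, os_ in zip(*km_naive(t, e)):
            assert s[ot] == pytest.approx(os_, abs=1e-10)


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_score_statistic_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        t1, t0 = rng.exponential(10, 25), rng.exponential(20, 30)
        e1, e0 = rng.integers(0, 2, 25), rng.integers(0, 2, 30)
        if e1.sum() + e0.sum() == 0:
            e1[0] = 1
        chi2, _ = logrank_test(t1, e1, t0, e0)
        assert chi2 == pytest.approx(logrank_naive(t1, e1, t0, e0), abs=1e-6)

    def test_power_with_strong_hazard_ratio(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(10):
            t_hi = rng.exponential(10, 100)
            t_lo = rng.exponential(30, 100)
            _, p = logrank_test(t_hi, np.ones(100), t_lo, np.ones(100))
            hits += p < 1e-4
        assert hits >= 9

    def test_single_event_hand_value(self):
        # one event in group A at t=1 with 2+2 at risk: O=1, E=0.5, V=0.25
        chi2, _ = logrank_test([1.0, 5.0], [1, 0], [3.0, 4.0], [0, 0])
        assert chi2 == pytest.approx((1 - 0.5) ** 2 / 0.25, abs=1e-9)


class TestCoxScreen:
    def test_recovers_log_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n) / np.exp(1.0 * x)
        kept, table = cox_univariate_screen(pd.DataFrame({"x": x}), t, np.ones(n), alpha=0.05)
        # beta is reported per SD of x; undo the standardisation
        beta = table.loc["x", "beta"] / x.std()
        assert beta == pytest.approx(1.0, abs=0.15)
        assert kept == ["x"]

    def test_constant_feature_flagged(self):
        t = np.arange(1.0, 21)
        feats = pd.DataFrame({"c": np.ones(20), "ok": np.linspace(0, 1, 20)})
        kept, table = cox_univariate_screen(feats, t, np.ones(20))
        assert table.loc["c", "flag"] == "constant"
        assert "c" not in kept

    def test_null_feature_rarely_kept(self):
        rng = np.random.default_rng(9)
        n = 80
        keeps = 0
        for _ in range(20):
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            kept, _ = cox_univariate_screen(pd.DataFrame({"x": x}), t, np.ones(n))
            keeps += bool(kept)
        assert keeps <= 5  # ~5% nominal; generous binomial slack


class TestRiskScoreAndTdRoc:
    def test_rsf_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)))
        t = rng.exponential(100, 40)
        e = rng.random(40) < 0.8
        a = fit_risk_score(X, t, e, seed=5, loocv=False, n_trees=50)
        b = fit_risk_score(X, t, e, seed=5, loocv=False, n_trees=50)
        pd.testing.assert_series_equal(a, b)

    def test_strong_signal_concordance(self):
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(2.0 * x)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        scores = fit_risk_score(X, t, np.ones(n), seed=0, loocv=False, n_trees=100)
        from sksurv.metrics import concordance_index_censored

        c = concordance_index_censored(np.ones(n, bool), t, scores.to_numpy())[0]
        assert c > 0.7

    def test_tdroc_reduces_to_static_auc_without_censoring(self, rng):
        n = 80
        scores = rng.normal(size=n)
        t = rng.exponential(100, n)
        horizon = float(np.median(t))
        auc_td = td_roc(scores, t, np.ones(n), horizon)
        auc_static = roc_auc(scores, (t <= horizon).astype(int))
        assert auc_td == pytest.approx(auc_static, abs=1e-10)

    def test_tdroc_null_near_half(self):
        rng = np.random.default_rng(3)
        n = 200
        scores = rng.normal(size=n)
        t = rng.exponential(200, n)
        c = rng.uniform(0, 600, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        assert td_roc(scores, obs, ev, 180.0) == pytest.approx(0.5, abs=0.1)

    def test_tdroc_requires_cases_and_controls(self, rng):
        with pytest.raises(ValueError):
            td_roc(rng.normal(size=5), [10, 20, 30, 40, 50], [1, 1, 1, 1, 1], 5.0)


class TestPfsPipeline:
    def test_median_split_balanced_and_summary_fields(self):
        syn = simulate_feature_cohort(
            SimulationConfig(n_patients=60, n_features=20, n_informative=5,
                             effect_size=1.0, pfs_coef=2.0, censor_rate=0.1, seed=4)
        )
        from dynrad import build_dynamic_matrix

        dyn = build_dynamic_matrix(syn.phases, kinds=["RCR"])
        res = pfs_pipeline(
            dyn.data.iloc[:, :30],
            syn.cohort["pfs_days"],
            syn.cohort["event"],
            SurvivalConfig(n_trees=50, seed=4, horizons=(90.0, 180.0)),
        )
        n_hi = (res.group == "high").sum()
        n_lo = (res.group == "low").sum()
        assert abs(n_hi - n_lo) <= 1
        assert 0 <= res.logrank_p <= 1
        assert set(res.tdauc) == {90.0, 180.0}
        assert len(res.risk_scores) == 60
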