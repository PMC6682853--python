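import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mvhist import synthetic
from mvhist.survival import (
    CoxModelResult,
    SurvivalRecord,
    cox_ph_fit,
    incremental_auc,
    kaplan_meier,
    log_rank_test,
    optimal_cutpoint,
    rank_features,
    twelve_month_outcome,
    two_sample_logrank,
)


def manual_logrank_z(times, events, group):
    """Independent O-E/variance tabulation, written longhand."""
    o_e, var = 0.0, 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(risk)
        n1 = sum(1 for i in risk if group[i])
        dead = [i for i, (ti, ei) in enumerate(zip(times, events)) if ei and ti == t]
        d = len(dead)
        d1 = sum(1 for i in dead if group[i])
        o_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e / np.sqrt(var)


class TestSurvivalRecord:
    def test_positive_times_enforced(self):
        with pytest.raises(ValueError):
            SurvivalRecord(os_days=0, os_event=True, pfs_days=1, pfs_event=False)


class TestLogRank:
    def test_hand_worked_six_patients(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, False, True, True, True]
        group = [True, False, True, False, True, False]
        z_manual = manual_logrank_z(times, events, group)
        chi2, z = two_sample_logrank(np.array(times), np.array(events), np.array(group))
        assert z == pytest.approx(z_manual, abs=1e-12)
        stat, p = log_rank_test(np.array(group).astype(int), times, events)
        assert stat == pytest.approx(z_manual**2, abs=1e-9)

    def test_identical_groups_null(self):
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1], bool)
        group = np.array([0] * 4 + [1] * 4)
        stat, p = log_rank_test(group, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            log_rank_test([1, 1, 1], [1.0, 2, 3], [True, True, True])

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            log_rank_test([0, 1], [1.0, 2.0], [False, False])

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(10, 40)
        events = rng.random(40) > 0.3
        group = rng.integers(0, 2, 40)
        s1, p1 = log_rank_test(group, times, events)
        s2, p2 = log_rank_test(1 - group, times, events)
        assert s1 == pytest.approx(s2)
        assert 0 <= p1 <= 1 and p1 == pytest.approx(p2)

    def test_power_under_hr032(self):
        cfg = synthetic.CohortConfig(hr_cluster2_os=0.32, censoring_rate=0.2)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            times, events, grp = [], [], []
            for i in range(500):
                cl = 1 if i % 2 else 2
                rec = synthetic.generate_survival(cl, cfg, rng=rng)
                times.append(rec.os_days)
                events.append(rec.os_event)
                grp.append(cl)
            _, p = log_rank_test(grp, times, events)
            hits += p < 0.001
        assert hits >= 95

    def test_matches_lifelines_two_sample(self, rng):
        # the in-house standardized statistic agrees with lifelines' chi2
        times = rng.exponential(5, 60)
        events = rng.random(60) > 0.25
        group = rng.integers(0, 2, 60).astype(bool)
        chi2, _ = two_sample_logrank(times, events, group)
        stat, _ = log_rank_test(group.astype(int), times, events)
        assert chi2 == pytest.approx(stat, rel=1e-9)


class TestKaplanMeier:
    def test_no_censoring_matches_empirical(self, rng):
        times = rng.exponential(5, 30)
        km = kaplan_meier(times, np.ones(30, bool))["all"]
        for t, s in zip(km["timeline"], km["survival"]):
            assert s == pytest.approx(np.mean(times > t))

    def test_all_censored_flat_one(self):
        km = kaplan_meier([1.0, 2, 3], [False] * 3)["all"]
        assert (km["survival"] == 1.0).all()

    def test_five_patient_hand_products(self):
        # times 1,2,3,4,5; events 1,1,0,1,0
        # S(1)=4/5, S(2)=4/5*3/4=3/5, S(4)=3/5*1/2=3/10
        km = kaplan_meier([1.0, 2, 3, 4, 5], [1, 1, 0, 1, 0])["all"]
        curve = dict(zip(km["timeline"], km["survival"]))
        assert curve[1.0] == pytest.approx(0.8)
        assert curve[2.0] == pytest.approx(0.6)
        assert curve[4.0] == pytest.approx(0.3)

    def test_grouped_medians(self):
        out = kaplan_meier(
            [1.0, 2, 3, 10, 20, 30],
            [1, 1, 1, 1, 1, 1],
            groups=[0, 0, 0, 1, 1, 1],
        )
        assert out[0]["median"] == pytest.approx(2.0)
        assert out[1]["median"] == pytest.approx(20.0)


class TestOptimalCutpoint:
    def test_cluster_indicator_recovered(self):
        values = np.array([0.0] * 5 + [1.0] * 5)
        times = np.array([1.0, 2, 3, 4, 5, 11, 12, 13, 14, 15])
        events = np.ones(10, bool)
        cut = optimal_cutpoint(values, times, events, min_prop=0.1)
        assert cut.cutoff == pytest.approx(0.5)
        assert (cut.groups == values).all()

    def test_matches_exhaustive_enumeration(self, rng):
        values = rng.normal(size=10)
        times = rng.exponential(5, 10)
        events = rng.random(10) > 0.2
        if not events.any():
            events[0] = True
        cut = optimal_cutpoint(values, times, events, min_prop=0.1)
        # brute force over every admissible midpoint
        uniq = np.sort(np.unique(values))
        best_c, best_z = None, -1.0
        for c in 0.5 * (uniq[:-1] + uniq[1:]):
            high = values > c
            if high.sum() < 1 or (~high).sum() < 1:
                continue
            z = abs(manual_logrank_z(times.tolist(), events.tolist(), high.tolist()))
            if z > best_z + 1e-12:
                best_c, best_z = c, z
        assert cut.cutoff == pytest.approx(best_c)
        assert cut.statistic == pytest.approx(best_z, abs=1e-10)

    def test_constant_values_raise(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1.0] * 5, [1.0, 2, 3, 4, 5], [True] * 5)

    def test_min_prop_respected(self):
        values = np.arange(10.0)
        times = np.arange(1.0, 11)
        events = np.ones(10, bool)
        cut = optimal_cutpoint(values, times, events, min_prop=0.3)
        assert 3 <= (values > cut.cutoff).sum() <= 7


class TestCoxFit:
    @staticmethod
    def _frame(times, events, x):
        return pd.DataFrame({"t": times, "e": events, "x": x})

    def test_constant_covariate_null(self):
        df = self._frame([1.0, 2, 3, 4], [1, 1, 1, 1], [2.0, 2, 2, 2])
        with pytest.warns(UserWarning, match="constant"):
            res = cox_ph_fit(df, "t", "e")
        assert res.hr("x") == 1.0
        assert res.p("x") == 1.0

    def test_binary_covariate_matches_grid_search(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True, True, True, True]
        x = [1.0, 0.0, 1.0, 0.0]
        res = cox_ph_fit(self._frame(times, events, x), "t", "e")

        def neg_pl(b):
            ll = 0.0
            for i in np.argsort(times):
                risk = [j for j in range(4) if times[j] >= times[i]]
                ll += b * x[i] - np.log(sum(np.exp(b * x[j]) for j in risk))
            return -ll

        grid = np.linspace(-6, 6, 24001)
        b0 = grid[int(np.argmin([neg_pl(b) for b in grid]))]
        opt = minimize_scalar(neg_pl, bracket=(b0 - 0.01, b0 + 0.01))
        assert np.log(res.hr("x")) == pytest.approx(opt.x, abs=1e-4)

    def test_binary_label_swap_reciprocal_hr(self, rng):
        times = rng.exponential(5, 50)
        events = rng.random(50) > 0.2
        x = rng.integers(0, 2, 50).astype(float)
        r1 = cox_ph_fit(self._frame(times, events, x), "t", "e")
        r2 = cox_ph_fit(self._frame(times, events, 1 - x), "t", "e")
        assert r1.hr("x") == pytest.approx(1 / r2.hr("x"), rel=1e-6)

    def test_ci_contains_hr(self, rng):
        times = rng.exponential(5, 60)
        events = rng.random(60) > 0.2
        x = rng.normal(size=60)
        res = cox_ph_fit(self._frame(times, events, x), "t", "e")
        row = res.summary.loc["x"]
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]
        assert row["hr"] > 0

    def test_breslow_selectable(self, rng):
        times = rng.exponential(5, 60).round(0) + 1  # induce ties
        events = rng.random(60) > 0.2
        x = rng.normal(size=60)
        efron = cox_ph_fit(self._frame(times, events, x), "t", "e", ties="efron")
        breslow = cox_ph_fit(self._frame(times, events, x), "t", "e", ties="breslow")
        # close but not identical in the presence of ties
        assert breslow.hr("x") == pytest.approx(efron.hr("x"), rel=0.1)
        with pytest.raises(ValueError):
            cox_ph_fit(self._frame(times, events, x), "t", "e", ties="exact")

    def test_few_events_warns(self):
        df = pd.DataFrame(
            {
                "t": [1.0, 2, 3, 4],
                "e": [True, False, False, False],
                "x": [0.1, 0.9, 0.4, 0.6],
                "y": [1.0, 0.0, 1.0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="events"):
            cox_ph_fit(df, "t", "e")

    def test_parameter_recovery_hr032(self):
        cfg = synthetic.CohortConfig(hr_cluster2_os=0.32, censoring_rate=0.2)
        rng = np.random.default_rng(5)
        rows = []
        for i in range(1000):
            cl = 1 if i % 2 else 2
            rec = synthetic.generate_survival(cl, cfg, rng=rng)
            rows.append((rec.os_days, rec.os_event, int(cl == 2)))
        df = pd.DataFrame(rows, columns=["t", "e", "cluster2"])
        res = cox_ph_fit(df, "t", "e")
        assert 0.25 <= res.hr("cluster2") <= 0.41


class TestRankFeatures:
    def test_dominant_feature_scores_100(self, rng):
        n = 60
        labels = np.array([1] * 30 + [2] * 30)
        X = pd.DataFrame(
            {
                "signal": (labels == 2) + rng.normal(0, 0.05, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        with pytest.warns(UserWarning):
            ranked = rank_features(X, labels)
        by_name = {r.name: r for r in ranked}
        assert by_name["signal"].importance == pytest.approx(100.0)
        assert by_name["signal"].selected

    def test_constant_feature_scores_zero(self, rng):
        n = 80
        labels = np.array([1] * 40 + [2] * 40)
        X = pd.DataFrame(
            {
                "informative": (labels == 2) * 1.0 + rng.normal(0, 1.0, n),
                "flat": np.ones(n),
            }
        )
        ranked = {r.name: r for r in rank_features(X, labels)}
        assert ranked["flat"].importance == pytest.approx(0.0)
        assert not ranked["flat"].selected

    def test_matches_manual_newton_oracle(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        logit = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        labels = np.where(y == 1, 2, 1)
        Xdf = pd.DataFrame(X, columns=["a", "b", "c"])
        ranked = {r.name: r.importance for r in rank_features(Xdf, labels)}

        # oracle: Newton MLE + Wald z from the inverse Hessian, by hand
        Z = (X - X.mean(0)) / X.std(0)
        Xd = np.column_stack([np.ones(n), Z])
        beta = np.zeros(4)
        for _ in range(50):
            mu = 1 / (1 + np.exp(-Xd @ beta))
            H = (Xd.T * (mu * (1 - mu))) @ Xd
            beta += np.linalg.solve(H, Xd.T @ (y - mu))
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        z = np.abs(beta[1:] / se[1:])
        expected = (z - z.min()) / (z.max() - z.min()) * 100
        for name, e in zip(["a", "b", "c"], expected):
            assert ranked[name] == pytest.approx(e, rel=1e-3)

    def test_requires_two_clusters(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            rank_features(X, np.ones(10))


class TestTwelveMonthOutcome:
    def test_classification(self):
        times = np.array([100.0, 400.0, 200.0, 365.0])
        events = np.array([True, True, False, False])
        out, n_ex = twelve_month_outcome(times, events)
        assert out[0] == 1  # died inside 12 months
        assert out[1] == 0  # died later -> alive at 12 months
        assert np.isnan(out[2])  # censored early -> undetermined
        assert out[3] == 0  # followed to the horizon
        assert n_ex == 1


class TestIncrementalAuc:
    def test_duplicated_feature_no_gain(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = (x + rng.normal(0, 1, n) > 0).astype(float)
        base = pd.DataFrame({"x": x})
        feat = pd.DataFrame({"x_copy": x})
        res = incremental_auc(base, feat, y, n_boot=100, seed=0)
        assert res.delta == pytest.approx(0.0, abs=1e-6)

    def test_perfect_feature_gives_auc_one(self, rng):
        n = 50
        y = rng.integers(0, 2, n).astype(float)
        base = pd.DataFrame({"noise": rng.normal(size=n)})
        feat = pd.DataFrame({"oracle": y + rng.normal(0, 1e-4, n)})
        res = incremental_auc(base, feat, y, n_boot=50, seed=0)
        assert res.auc_augmented == pytest.approx(1.0, abs=1e-9)

    def test_nested_auc_ordering(self, rng):
        n = 80
        x = rng.normal(size=(n, 2))
        y = (x[:, 0] + rng.normal(0, 1, n) > 0).astype(float)
        res = incremental_auc(
            pd.DataFrame(x[:, :1]), pd.DataFrame(x[:, 1:]), y, n_boot=50, seed=1
        )
        assert res.auc_augmented >= res.auc_baseline - 1e-9
        assert 0 <= res.p_value <= 1

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            incremental_auc(
                pd.DataFrame({"a": rng.normal(size=10)}),
                pd.DataFrame({"b": rng.normal(size=10)}),
                np.ones(10),
                n_boot=10,
            )

    def test_nan_outcomes_excluded(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        y[:5] = np.nan
        res = incremental_auc(
            pd.DataFrame({"x": x}), pd.DataFrame({"z": rng.normal(size=n)}),
            y, n_boot=20, seed=0,
        )
        assert np.isfinite(res.auc_baseline)
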