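import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilnc import survival as sv
from oracles import km_oracle


def records(times, events, **covs):
    n = len(times)
    df = pd.DataFrame({"time": times, "event": events},
                      index=[f"s{i}" for i in range(n)])
    for k, v in covs.items():
        df[k] = v
    return df


def simulate_cohort(n, log_hr, rng, censor_scale=3.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(log_hr * x)))
    c = rng.uniform(0, censor_scale / 0.1, n)
    return records(np.minimum(t, c), (t <= c).astype(int), x=x)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        out = sv.km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert np.allclose(out["survival"], 1.0)

    def test_all_events_product_limit(self):
        out = sv.km_estimate(records([1, 2, 3], [1, 1, 1]))
        assert np.allclose(out["survival"], [2 / 3, 1 / 3, 0.0])
        assert list(out["at_risk"]) == [3, 2, 1]

    def test_duplicating_cohort_leaves_curve_unchanged(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 20)
        e = rng.integers(0, 2, 20)
        single = sv.km_estimate(records(t, e))
        double = sv.km_estimate(records(np.concatenate([t, t]),
                                        np.concatenate([e, e])))
        assert np.allclose(single["survival"], double["survival"])

    def test_matches_product_limit_oracle_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            t = rng.integers(1, 5, n).astype(float)  # force ties
            e = rng.integers(0, 2, n)
            ours = sv.km_estimate(records(t, e))
            expected = km_oracle(t, e)
            assert len(ours) == len(expected)
            for row, (et, at_risk, d, s) in zip(ours.itertuples(index=False), expected):
                assert row.time == et and row.at_risk == at_risk and row.observed == d
                assert row.survival == pytest.approx(s, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sv.km_estimate(records([-1, 2], [1, 1]))


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0]
        rec = records(t + t, e + e)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=rec.index)
        chi2, p = sv.logrank_test(rec, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            rec = records(rng.exponential(5, 40), rng.integers(0, 2, 40))
            groups = pd.Series(rng.integers(0, 2, 40), index=rec.index)
            if groups.nunique() < 2 or rec["event"].sum() == 0:
                continue
            pvals.append(sv.logrank_test(rec, groups)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_hazard_ratio_3(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 20
        for _ in range(reps):
            rec = simulate_cohort(200, np.log(3.0), rng)
            groups = pd.Series(rec["x"].map({0.0: "lo", 1.0: "hi"}), index=rec.index)
            if sv.logrank_test(rec, groups)[1] < 0.01:
                hits += 1
        assert hits >= int(0.85 * reps)

    def test_single_group_rejected(self):
        rec = records([1, 2], [1, 1])
        with pytest.raises(ValueError):
            sv.logrank_test(rec, pd.Series(["a", "a"], index=rec.index))


class TestCoxFit:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        rec = simulate_cohort(500, 0.0, rng)
        fit = sv.cox_fit(rec, ["x"])
        assert fit.converged
        assert abs(fit.coefficients["x"]) < 0.25
        assert fit.loglik <= 0

    def test_duplicate_covariate_rejected(self):
        rng = np.random.default_rng(5)
        rec = simulate_cohort(100, 0.5, rng)
        rec["x_copy"] = rec["x"]
        with pytest.raises(ValueError):
            sv.cox_fit(rec, ["x", "x_copy"])

    def test_nested_model_loglik_monotone(self):
        rng = np.random.default_rng(6)
        rec = simulate_cohort(300, 0.7, rng)
        rec["noise"] = rng.normal(size=300)
        base = sv.cox_fit(rec, ["x"])
        full = sv.cox_fit(rec, ["x", "noise"])
        assert full.loglik >= base.loglik - 1e-6

    def test_null_loglik_matches_lifelines_lr_test(self):
        rng = np.random.default_rng(7)
        rec = simulate_cohort(150, 0.7, rng)
        fit = sv.cox_fit(rec, ["x"])
        lr_ours = 2.0 * (fit.loglik - sv.null_loglik(rec))
        from lifelines import CoxPHFitter
        cph = CoxPHFitter().fit(rec[["time", "event", "x"]], "time", "event")
        assert lr_ours == pytest.approx(
            cph.log_likelihood_ratio_test().test_statistic, rel=1e-6
        )


class TestLRLadder:
    def _cohort(self, seed=8, n=300):
        rng = np.random.default_rng(seed)
        rec = simulate_cohort(n, 0.8, rng)
        rec["age"] = rng.normal(55, 10, n)
        rec["gender"] = rng.choice(["male", "female"], n)
        rec["noise"] = rng.normal(size=n)
        return rec

    def test_duplicated_base_covariate_gives_exact_zero(self):
        rec = self._cohort()
        rec["age_copy"] = rec["age"]
        ladder = sv.lr_ladder(rec, ["age_copy", "x"])
        assert ladder.loc["age_copy", "lr"] == 0.0
        assert ladder.loc["age_copy", "p"] == 1.0

    def test_lr_non_negative_and_informative_feature_wins(self):
        rec = self._cohort()
        ladder = sv.lr_ladder(rec, ["x", "noise"])
        assert (ladder["lr"] >= -1e-6).all()
        assert ladder.loc["x", "lr"] > ladder.loc["noise", "lr"]
        assert ladder.loc["x", "p"] < 0.01


class TestStepwise:
    def _cohort(self, seed, n=400):
        rng = np.random.default_rng(seed)
        rec = simulate_cohort(n, 1.0, rng)
        for i in range(4):
            rec[f"noise{i}"] = rng.normal(size=n)
        return rec

    def test_true_predictor_selected(self):
        found = 0
        for seed in range(5):
            rec = self._cohort(seed)
            selected, fit = sv.stepwise_cox(rec, ["x"] + [f"noise{i}" for i in range(4)])
            if "x" in selected:
                found += 1
        assert found >= 4

    def test_duplicate_feature_selected_once(self):
        rec = self._cohort(10)
        selected, _ = sv.stepwise_cox(rec, ["x", "x", "noise0"])
        assert selected.count("x") <= 1

    def test_pure_noise_rarely_selected(self):
        # under AIC the best of 4 noise features clears the penalty with
        # probability P(max chi2_1 > 2) ~ 0.5, so require only that the
        # selected sets stay small and are often empty
        empties, total = 0, 0
        for seed in range(12):
            rec = self._cohort(seed + 20)
            selected, _ = sv.stepwise_cox(rec, [f"noise{i}" for i in range(4)])
            empties += not selected
            total += len(selected)
        assert empties >= 2
        assert total / 12 <= 1.5


class TestTMBAndEnrichment:
    def test_tmb_values(self):
        counts = pd.Series([80, 0, 40], index=["a", "b", "c"])
        tmb = sv.compute_tmb(counts)
        assert list(tmb) == [2.0, 0.0, 1.0]
        with pytest.raises(ValueError):
            sv.compute_tmb(pd.Series([-1]))

    def test_identical_labelings_closed_form(self):
        idx = [f"s{i}" for i in range(20)]
        a = pd.Series(["x"] * 10 + ["y"] * 10, index=idx)
        out = sv.hypergeometric_enrichment(a, a)
        from math import comb
        assert out.loc["x", "x"] == pytest.approx(1.0 / comb(20, 10))
        assert out.loc["x", "y"] == pytest.approx(1.0)

    def test_class_covering_all_samples_gives_p1(self):
        idx = [f"s{i}" for i in range(10)]
        a = pd.Series(["x"] * 5 + ["y"] * 5, index=idx)
        b = pd.Series(["all"] * 10, index=idx)
        out = sv.hypergeometric_enrichment(a, b)
        assert np.allclose(out.to_numpy(dtype=float), 1.0)

    def test_independent_labels_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            idx = [f"s{i}" for i in range(40)]
            a = pd.Series(rng.choice(["x", "y"], 40), index=idx)
            b = pd.Series(rng.choice(["u", "v"], 40), index=idx)
            out = sv.hypergeometric_enrichment(a, b)
            pvals.append(float(out.iloc[0, 0]))
        # discrete upper-tail p-values are super-uniform: conservative check
        assert np.mean(np.array(pvals) < 0.05) <= 0.08
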