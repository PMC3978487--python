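import math

import numpy as np
import pandas as pd
import pytest

from poolmark import (
    DataError,
    adjust_pvalues,
    analyze_pooled,
    build_pooled_cohort,
    cox_hr,
    km_estimate,
    logrank_test,
)
from poolmark.survival_stats import PooledCohort
from conftest import make_bundle
from poolmark.grouping import CutoffRule, GroupAssignment
from _oracles import km_oracle, logrank_oracle, random_small_cohort


def cohort_from(time, event, group, dataset="d1", endpoint="dfs"):
    return PooledCohort(
        endpoint,
        pd.DataFrame(
            {"time": np.asarray(time, float), "event": np.asarray(event, float),
             "group": list(group), "dataset_id": dataset}
        ),
    )


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        c = cohort_from([1, 2, 3, 4, 5, 1, 2], [1, 1, 0, 1, 0, 0, 0],
                        ["high"] * 5 + ["low"] * 2)
        km = km_estimate(c)
        high = km.curves["high"].set_index("time")["survival"]
        assert high[1.0] == pytest.approx(0.8)
        assert high[2.0] == pytest.approx(0.6)
        assert high[4.0] == pytest.approx(0.3)

    def test_all_censored_flat_curve(self):
        c = cohort_from([1, 2, 3, 4], [0, 0, 0, 0], ["high", "high", "low", "low"])
        km = km_estimate(c)
        assert (km.curves["high"]["survival"] == 1.0).all()
        assert (km.curves["low"]["survival"] == 1.0).all()

    def test_single_subject_step_to_zero(self):
        c = cohort_from([3, 5], [1, 0], ["high", "low"])
        km = km_estimate(c)
        assert km.survival_at("high", 2.9) == 1.0
        assert km.survival_at("high", 3.0) == 0.0

    def test_empty_group_raises(self):
        c = cohort_from([1, 2], [1, 1], ["high", "high"])
        with pytest.raises(DataError, match="empty group"):
            km_estimate(c)

    def test_survival_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(11)
        c = cohort_from(rng.exponential(10, 60), rng.random(60) < 0.6,
                        np.where(rng.random(60) < 0.5, "high", "low"))
        km = km_estimate(c)
        for df in km.curves.values():
            s = df["survival"].to_numpy()
            assert ((s >= 0) & (s <= 1)).all()
            assert (np.diff(s) <= 1e-15).all()


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        c = cohort_from(t + t, e + e, ["high"] * 4 + ["low"] * 4)
        chi2, p = logrank_test(c)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        c = cohort_from([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 0, 1],
                        ["high", "high", "low", "high", "low", "low"])
        chi2, p = logrank_test(c)
        ochi2, op = logrank_oracle(c.records["time"], c.records["event"],
                                   c.records["group"] == "high")
        assert chi2 == pytest.approx(ochi2, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)

    def test_no_events_raises(self):
        c = cohort_from([1, 2], [0, 0], ["high", "low"])
        with pytest.raises(DataError, match="no events"):
            logrank_test(c)

    def test_label_swap_invariant(self):
        rng = np.random.default_rng(2)
        g = np.where(rng.random(40) < 0.5, "high", "low")
        t, e = rng.exponential(10, 40), (rng.random(40) < 0.7).astype(float)
        chi2_a, _ = logrank_test(cohort_from(t, e, g))
        chi2_b, _ = logrank_test(cohort_from(t, e, np.where(g == "high", "low", "high")))
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        n = 120
        t = rng.exponential(20, n).round(1) + 0.1
        e = (rng.random(n) < 0.7).astype(float)
        g = rng.random(n) < 0.5
        chi2, p = logrank_test(cohort_from(t, e, np.where(g, "high", "low")))
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_null_simulation_type_i_error(self):
        """Rejection rate at alpha=0.05 within the 99% binomial band (null data)."""
        rng = np.random.default_rng(99)
        reps, n = 1000, 200
        rejections = 0
        for _ in range(reps):
            t = rng.exponential(30, n)
            e = (rng.random(n) < 0.7).astype(float)
            g = np.where(np.arange(n) < n // 2, "high", "low")
            _, p = logrank_test(cohort_from(t, e, g))
            rejections += p < 0.05
        rate = rejections / reps
        band = 2.576 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < band


class TestOracleEquivalence:
    def test_small_cohorts_match_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            df = random_small_cohort(rng)
            c = PooledCohort("dfs", df)
            chi2, p = logrank_test(c)
            ochi2, _ = logrank_oracle(df["time"], df["event"], df["group"] == "high")
            assert abs(chi2 - ochi2) <= 1e-12
            km = km_estimate(c)
            for grp in ("high", "low"):
                sub = df[df["group"] == grp]
                expected = dict(km_oracle(sub["time"], sub["event"]))
                got = km.curves[grp]
                for t, row_s, d in zip(got["time"], got["survival"], got["n_events"]):
                    if d > 0:
                        assert abs(row_s - expected[t]) <= 1e-12


class TestCox:
    def test_identical_groups_hr_one(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 0, 1, 1]
        c = cohort_from(t + t, e + e, ["high"] * 5 + ["low"] * 5)
        r = cox_hr(c)
        assert abs(r.beta) < 1e-6
        assert r.hr == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_exact_reciprocal(self):
        rng = np.random.default_rng(8)
        n = 150
        t = rng.exponential(25, n)
        e = (rng.random(n) < 0.7).astype(float)
        g = np.where(rng.random(n) < 0.4, "high", "low")
        r = cox_hr(cohort_from(t, e, g))
        r_swap = cox_hr(cohort_from(t, e, np.where(g == "high", "low", "high")))
        assert r_swap.beta == -r.beta
        assert r.hr * r_swap.hr == pytest.approx(1.0, abs=1e-12)

    def test_time_rescaling_leaves_beta_unchanged(self):
        rng = np.random.default_rng(9)
        n = 100
        t = rng.exponential(25, n)
        e = (rng.random(n) < 0.6).astype(float)
        g = np.where(rng.random(n) < 0.5, "high", "low")
        r1 = cox_hr(cohort_from(t, e, g))
        r2 = cox_hr(cohort_from(t * 37.25, e, g))
        assert abs(r2.beta - r1.beta) <= 1e-10

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(10)
        n = 200
        g = rng.random(n) < 0.5
        t = rng.exponential(np.where(g, 10, 20)).round(0) + 1.0  # ties on purpose
        e = (rng.random(n) < 0.8).astype(float)
        r = cox_hr(cohort_from(t, e, np.where(g, "high", "low")))
        df = pd.DataFrame({"t": t, "e": e, "x": g.astype(float)})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert r.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert r.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_separation_flagged_not_raised(self):
        c = cohort_from([1, 2, 3, 4], [1, 1, 0, 0], ["high", "high", "low", "low"])
        r = cox_hr(c)
        assert r.separation
        assert r.hr == math.inf
        assert r.hr_ci_high == math.inf and r.hr_ci_low == 0.0

    def test_duplicated_cohort_same_hr_smaller_ci(self):
        rng = np.random.default_rng(12)
        n = 120
        g = rng.random(n) < 0.5
        t = rng.exponential(np.where(g, 10, 18), n)
        e = (rng.random(n) < 0.8).astype(float)
        c1 = cohort_from(t, e, np.where(g, "high", "low"))
        c2 = cohort_from(
            np.concatenate([t, t]), np.concatenate([e, e]),
            np.concatenate([np.where(g, "high", "low")] * 2),
        )
        r1, r2 = cox_hr(c1), cox_hr(c2)
        # duplication preserves the point estimate exactly under Breslow;
        # the Efron correction for the duplicated ties perturbs it slightly
        assert r2.beta == pytest.approx(r1.beta, rel=0.05, abs=0.02)
        assert (r2.hr_ci_high - r2.hr_ci_low) < (r1.hr_ci_high - r1.hr_ci_low)

    def test_stratified_vs_pooled_differ_under_baseline_shift(self):
        rng = np.random.default_rng(13)
        frames = []
        for ds, scale in [("a", 5.0), ("b", 50.0)]:
            n = 150
            g = rng.random(n) < 0.5
            t = rng.exponential(np.where(g, scale / 2, scale), n)
            frames.append(pd.DataFrame(
                {"time": t, "event": 1.0, "group": np.where(g, "high", "low"),
                 "dataset_id": ds}))
        c = PooledCohort("dfs", pd.concat(frames, ignore_index=True))
        pooled = cox_hr(c, stratify_by_dataset=False)
        strat = cox_hr(c, stratify_by_dataset=True)
        assert strat.beta != pooled.beta
        assert strat.hr == pytest.approx(2.0, rel=0.25)


class TestPooling:
    def _assignment(self, ds, labels, samples):
        return GroupAssignment(ds, ("g",), CutoffRule.MEDIAN,
                               pd.Series(labels, index=samples))

    def test_endpoint_missing_dataset_contributes_nothing(self):
        b1 = make_bundle("d1", ["g"], {"g": [1.0, 2.0, 3.0, 4.0]},
                         dfs_time=[5.0, 6.0, 7.0, 8.0], dfs_event=[1.0, 1.0, 0.0, 1.0])
        b2 = make_bundle("d2", ["g"], {"g": [1.0, 2.0]},
                         os_time=[9.0, 10.0], os_event=[1.0, 0.0])
        clinical = {"d1": b1.clinical, "d2": b2.clinical}
        a1 = self._assignment("d1", ["low", "low", "high", "high"], b1.sample_ids)
        a2 = self._assignment("d2", ["low", "high"], b2.sample_ids)
        cohort = build_pooled_cohort([a1, a2], clinical, "dfs")
        assert cohort.n == 4
        assert cohort.per_dataset_n == {"d1": 4}

    def test_excluded_samples_dropped(self):
        b = make_bundle("d1", ["g"], {"g": [1.0, 2.0, 3.0, 4.0]},
                        dfs_time=[5.0, 6.0, 7.0, 8.0], dfs_event=[1.0, 1.0, 0.0, 1.0])
        a = self._assignment("d1", ["low", "excluded", "high", "high"], b.sample_ids)
        cohort = build_pooled_cohort([a], {"d1": b.clinical}, "dfs")
        assert cohort.n == 3

    def test_single_group_cohort_raises(self):
        b = make_bundle("d1", ["g"], {"g": [1.0, 2.0]},
                        dfs_time=[5.0, 6.0], dfs_event=[1.0, 1.0])
        a = self._assignment("d1", ["low", "low"], b.sample_ids)
        with pytest.raises(DataError, match="single-group"):
            analyze_pooled([a], {"d1": b.clinical}, "dfs")


def test_bh_adjustment_monotone():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    adj = adjust_pvalues(p)
    assert (np.diff(adj) >= -1e-15).all()
    assert (adj >= np.asarray(p) - 1e-15).all()
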