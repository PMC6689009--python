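"""Survival statistics: KM, logrank, Cox/BIC, relative odds, enrichment, H-score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import sigstrat as ss
from sigstrat.errors import ValidationError
from sigstrat.survstats import _null_partial_loglik


def surv_frame(times, events, groups):
    return pd.DataFrame(
        {"time_months": times, "event": events, "group": groups},
        index=[f"s{i}" for i in range(len(times))],
    )


class TestKMMedian:
    def test_uncensored_step_median(self):
        surv = surv_frame([1, 2, 3], [1, 1, 1], ["a"] * 3)
        km = ss.km_median(surv)
        assert km.loc["a", "median_months"] == 2.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10.0, size=40)
        surv = surv_frame(times, [1] * 40, ["a"] * 40)
        km = ss.km_median(surv)
        curve = km.attrs["curves"]["a"]
        for t in times:
            ecdf = (times > t).mean()
            assert curve.loc[t].iloc[0] == pytest.approx(ecdf, abs=1e-12)

    def test_median_not_reached_reported_infinite(self):
        surv = surv_frame([5, 6, 7, 8], [1, 0, 0, 0], ["a"] * 4)
        km = ss.km_median(surv)
        assert math.isinf(km.loc["a", "median_months"])


def brute_force_logrank(surv):
    """Direct O/E/V enumeration over event times (two groups)."""
    g = sorted(surv["group"].unique())
    o_minus_e, var = 0.0, 0.0
    for t in sorted(surv.loc[surv["event"] == 1, "time_months"].unique()):
        at_risk = surv[surv["time_months"] >= t]
        d = ((surv["time_months"] == t) & (surv["event"] == 1)).sum()
        n = len(at_risk)
        n1 = (at_risk["group"] == g[0]).sum()
        d1 = (
            (surv["time_months"] == t)
            & (surv["event"] == 1)
            & (surv["group"] == g[0])
        ).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        base = surv_frame([1, 2, 3, 4], [1, 1, 0, 1], ["a"] * 4)
        dup = base.copy()
        dup["group"] = "b"
        dup.index = [f"d{i}" for i in range(4)]
        stat, p = ss.logrank(pd.concat([base, dup]))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_manual_table_oracle(self):
        surv = surv_frame(
            [1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1], ["a", "a", "a", "b", "b", "b"]
        )
        stat, p = ss.logrank(surv)
        assert stat == pytest.approx(brute_force_logrank(surv), rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-9)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(1)
        surv = surv_frame(
            rng.exponential(5, 30), rng.integers(0, 2, 30), ["a"] * 15 + ["b"] * 15
        )
        s1, _ = ss.logrank(surv)
        surv2 = surv.assign(time_months=surv["time_months"] ** 2)
        s2, _ = ss.logrank(surv2)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            ss.logrank(surv_frame([1, 2], [1, 1], ["a", "a"]))

    def test_strong_separation_power(self):
        hits = 0
        for seed in range(5):
            _, surv, _ = ss.gen_cohort(ss.CohortConfig(n_samples=200, seed=40 + seed))
            _, p = ss.logrank(surv)
            hits += p < 1e-6
        assert hits == 5


class TestBicCompare:
    def test_null_model_definition(self):
        _, surv, _ = ss.gen_cohort(ss.CohortConfig(n_samples=100, seed=50))
        table = ss.bic_compare(surv, {"null": []})
        ll0 = _null_partial_loglik(
            surv["time_months"].to_numpy(), surv["event"].to_numpy()
        )
        assert table.loc["null", "k"] == 0
        assert table.loc["null", "bic"] == pytest.approx(-2 * ll0)

    def test_null_loglik_consistent_with_lifelines_lr_test(self):
        from lifelines import CoxPHFitter

        _, surv, _ = ss.gen_cohort(ss.CohortConfig(n_samples=150, seed=51))
        df = surv[["time_months", "event", "age"]].copy()
        cph = CoxPHFitter().fit(df, "time_months", "event")
        lr = cph.log_likelihood_ratio_test().test_statistic
        ll0_ll = cph.log_likelihood_ - lr / 2
        ll0 = _null_partial_loglik(
            surv["time_months"].to_numpy(), surv["event"].to_numpy()
        )
        assert ll0 == pytest.approx(ll0_ll, abs=1e-6)

    def test_planted_class_model_wins_decisively(self):
        _, surv, _ = ss.gen_cohort(ss.CohortConfig(n_samples=500, seed=52))
        table = ss.bic_compare(surv, {"class": ["group"], "age": ["age"]})
        assert table.index[0] == "class"
        assert table.loc["age", "delta_bic"] >= 10
        assert bool(table.loc["class", "meaningful"])

    def test_bic_invariant_to_covariate_scaling(self):
        _, surv, _ = ss.gen_cohort(ss.CohortConfig(n_samples=200, seed=53))
        t1 = ss.bic_compare(surv, {"age": ["age"]})
        surv2 = surv.assign(age=surv["age"] * 1000.0)
        t2 = ss.bic_compare(surv2, {"age": ["age"]})
        assert t1.loc["age", "bic"] == pytest.approx(t2.loc["age", "bic"], abs=1e-4)


def brute_force_relative_odds(score, phenotype):
    """Explicit extreme-fifths 2x2 odds ratio, computed independently."""
    df = pd.DataFrame({"s": score, "y": phenotype.astype(bool)})
    df["_id"] = df.index.astype(str)
    df = df.sort_values(["s", "_id"], kind="stable")
    k = math.ceil(len(df) / 5)
    top, bot = df.iloc[-k:], df.iloc[:k]
    a, b = top["y"].sum(), (~top["y"]).sum()
    c, d = bot["y"].sum(), (~bot["y"]).sum()
    if b == 0 or c == 0:
        return math.inf if a > 0 and d > 0 else math.nan
    if a == 0 or d == 0:
        return 0.0
    return (a / b) / (c / d)


class TestRelativeOdds:
    def test_constructed_counts_give_four(self):
        # n=15 -> extreme fifths of 3; top 2-of-3 vs bottom 1-of-3 positive
        score = pd.Series(range(15), index=[f"s{i:02d}" for i in range(15)])
        pheno = pd.Series(False, index=score.index)
        pheno[["s14", "s13", "s00"]] = True  # 2 in top; 1 in bottom
        ro = ss.relative_odds(score, pheno)
        assert ro.odds_ratio == pytest.approx((2 / 1) / (1 / 2))
        assert not ro.degenerate

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(10, 60))
            score = pd.Series(
                rng.normal(size=n).round(1), index=[f"x{i:03d}" for i in range(n)]
            )
            pheno = pd.Series(rng.random(n) < 0.4, index=score.index)
            if pheno.all() or (~pheno).all():
                continue
            ro = ss.relative_odds(score, pheno)
            ref = brute_force_relative_odds(score, pheno)
            if math.isnan(ref):
                assert math.isnan(ro.odds_ratio)
            else:
                assert ro.odds_ratio == ref
                assert ro.degenerate == (
                    ro.p_top in (0.0, 1.0) or ro.p_bottom in (0.0, 1.0)
                )

    def test_independence_gives_or_near_one(self):
        rng = np.random.default_rng(8)
        ors = []
        for _ in range(200):
            score = pd.Series(rng.normal(size=50))
            pheno = pd.Series(rng.random(50) < 0.5)
            if pheno.nunique() < 2:
                continue
            ro = ss.relative_odds(score, pheno)
            if np.isfinite(ro.odds_ratio) and ro.odds_ratio > 0:
                ors.append(math.log(ro.odds_ratio))
        assert abs(np.mean(ors)) < 0.2

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            ss.relative_odds(pd.Series(range(5)), pd.Series([True, False] * 2 + [True]))


class TestEnrichment:
    def test_perfect_separation_uses_fisher_exact(self):
        calls = pd.Series(["high"] * 10 + ["low"] * 10)
        labels = pd.Series(["WT"] * 10 + ["Mut"] * 10)
        res = ss.enrichment_table(calls, labels)
        assert res.test == "fisher"
        # exhaustive hypergeometric: only 1 of C(20,10) tables in each tail
        expected = 2 * stats.hypergeom.pmf(10, 20, 10, 10)
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            calls = pd.Series(rng.choice(["high", "low"], 60))
            labels = pd.Series(rng.choice(["x", "y", "z"], 60))
            try:
                ps.append(ss.enrichment_table(calls, labels).p)
            except ValidationError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            ss.enrichment_table(pd.Series(["a"] * 5), pd.Series(["x", "y"] * 2 + ["x"]))


class TestHScore:
    @pytest.mark.parametrize(
        "w,m,s,expected", [(0, 0, 0, 0.0), (0, 0, 100, 3.0), (50, 25, 25, 1.75)]
    )
    def test_closed_form(self, w, m, s, expected):
        assert ss.h_score(w, m, s) == expected

    def test_sum_above_hundred_rejected(self):
        with pytest.raises(ValidationError):
            ss.h_score(60, 30, 30)

    @given(
        w=st.floats(0, 100), m=st.floats(0, 100), s=st.floats(0, 100)
    )
    def test_bounded_in_unit_interval_times_three(self, w, m, s):
        if w + m + s > 100:
            return
        assert 0.0 <= ss.h_score(w, m, s) <= 3.0


class TestAssoc:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert ss.assoc(x, x)[0] == pytest.approx(1.0)
        assert ss.assoc(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_hand_example_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        r, _ = ss.assoc(x, y)
        ref = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ss.assoc([1, 1, 1], [1, 2, 3])
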