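"""Aggregation, repeated-measures ANOVA and Tukey post-hoc tests.

Oracles: explicit loop-based sums-of-squares arithmetic, numerical
integration of the studentized-range distribution, and the pingouin
implementation of the within-subject ANOVA as an independent library
cross-check.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sst

from ybalance.stats import (
    aggregate_trials,
    compare_conditions,
    condition_order,
    rm_anova,
    summarize,
    tukey_posthoc,
)


def make_table(y, conditions=("NT", "ST", "KT"), channel="ch", measure="m"):
    rows = [
        {"subject": f"s{i:02d}", "condition": cond, "channel": channel, "measure": measure,
         "value": y[i, j]}
        for i in range(y.shape[0])
        for j, cond in enumerate(conditions)
    ]
    return pd.DataFrame(rows)


def hand_within_subject_f(y):
    """Textbook long-form sums-of-squares arithmetic, all loops."""
    n, c = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(c)) / (n * c)
    ss_cond = sum(n * (sum(y[i][j] for i in range(n)) / n - grand) ** 2 for j in range(c))
    ss_subj = sum(c * (sum(y[i][j] for j in range(c)) / c - grand) ** 2 for i in range(n))
    ss_total = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(c))
    ss_err = ss_total - ss_subj - ss_cond
    return (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (n - 1)))


def studentized_range_sf_integrated(q, k, df):
    """P(Q > q) for the studentized range by direct double integration.

    Conditions on the scale estimate s = sqrt(chi2_df / df) and
    integrates the classical range probability over the normal density.
    Entirely independent of scipy.stats.studentized_range.
    """

    def cdf_given_s(s):
        def inner(z):
            return sst.norm.pdf(z) * (sst.norm.cdf(z) - sst.norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(inner, -9, 9, epsabs=1e-11, limit=200)
        return k * val

    def chi_scaled_pdf(s):
        # density of sqrt(chi2_df/df)
        return sst.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df)

    val, _ = integrate.quad(
        lambda s: chi_scaled_pdf(s) * cdf_given_s(s), 0, np.inf, epsabs=1e-10, limit=200
    )
    return 1.0 - val


class TestAggregateTrials:
    def test_mean_of_trials(self):
        rows = [
            {"subject": "a", "condition": "NT", "channel": "c", "measure": "hdf",
             "trial": t, "value": v}
            for t, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0], start=1)
        ]
        out = aggregate_trials(pd.DataFrame(rows))
        assert len(out) == 1
        assert out["value"].iloc[0] == 3.0

    def test_identical_trials_unchanged(self):
        rows = [
            {"subject": "a", "condition": "NT", "channel": "c", "measure": "hdf",
             "trial": t, "value": 1.7}
            for t in range(1, 6)
        ]
        assert aggregate_trials(pd.DataFrame(rows))["value"].iloc[0] == 1.7

    def test_missing_trial_averages_remaining(self):
        rows = [
            {"subject": "a", "condition": "NT", "channel": "c", "measure": "hdf",
             "trial": t, "value": v}
            for t, v in [(1, 2.0), (2, 4.0), (3, 6.0), (4, 8.0)]  # trial 5 missing
        ]
        assert aggregate_trials(pd.DataFrame(rows))["value"].iloc[0] == 5.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            aggregate_trials(pd.DataFrame({"subject": ["a"], "value": [1.0]}))


class TestSummarize:
    def test_constant_values(self):
        t = make_table(np.ones((3, 3)))
        out = summarize(t)
        assert (out["mean"] == 1.0).all() and (out["se"] == 0.0).all()

    def test_two_subject_se(self):
        t = make_table(np.array([[0.0], [2.0]]), conditions=("NT",))
        out = summarize(t)
        assert out["mean"].iloc[0] == 1.0 and out["se"].iloc[0] == 1.0

    def test_single_subject_rejected(self):
        t = make_table(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError):
            summarize(t)

    def test_condition_output_order_fixed(self):
        t = make_table(np.random.default_rng(0).random((4, 3)), conditions=("KT", "NT", "ST"))
        out = summarize(t)
        assert list(out["condition"]) == ["NT", "ST", "KT"]


class TestRmAnova:
    def test_matches_hand_computed_sums_of_squares(self, toy_table):
        table, y = toy_table
        f, df1, df2, p = rm_anova(table, "ch", "m")
        assert f == pytest.approx(hand_within_subject_f(y), abs=1e-10)
        assert f == pytest.approx(79.0 / 9.0, abs=1e-10)
        assert (df1, df2) == (2, 8)
        assert p == pytest.approx(sst.f.sf(79.0 / 9.0, 2, 8), abs=1e-12)

    def test_one_way_mode(self, toy_table):
        table, y = toy_table
        f, df1, df2, _ = rm_anova(table, "ch", "m", mode="one_way")
        f_scipy, _ = sst.f_oneway(*(y[:, j] for j in range(3)))
        assert (df1, df2) == (2, 12)
        assert f == pytest.approx(f_scipy, abs=1e-10)

    @pytest.mark.parametrize("n, df2_ws, df2_ow", [(5, 8, 12), (41, 80, 120)])
    def test_degrees_of_freedom(self, n, df2_ws, df2_ow):
        y = np.random.default_rng(n).random((n, 3))
        t = make_table(y)
        assert rm_anova(t, "ch", "m")[1:3] == (2, df2_ws)
        assert rm_anova(t, "ch", "m", mode="one_way")[1:3] == (2, df2_ow)

    def test_equal_condition_means_give_f_zero(self):
        subj = np.array([0.0, 3.0, 8.0, 1.0])
        y = subj[:, None] + np.zeros((4, 3))
        f, *_ = rm_anova(make_table(y), "ch", "m")
        assert f == 0.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = rng.standard_normal((7, 3)) + rng.standard_normal((7, 1))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(7), 3),
                    "cond": ["NT", "ST", "KT"] * 7,
                    "y": y.ravel(),
                }
            )
            ref = pg.rm_anova(df, dv="y", within="cond", subject="subject")
            f, df1, df2, p = rm_anova(make_table(y), "ch", "m")
            assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
            assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_subject_shift_invariance(self):
        # adding arbitrary per-subject constants must not change F
        rng = np.random.default_rng(9)
        y = rng.standard_normal((10, 3))
        shifted = y + rng.standard_normal((10, 1)) * 50.0
        f1, *_ = rm_anova(make_table(y), "ch", "m")
        f2, *_ = rm_anova(make_table(shifted), "ch", "m")
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_incomplete_subject_dropped_with_warning(self):
        y = np.random.default_rng(1).random((5, 3))
        t = make_table(y)
        t = t[~((t["subject"] == "s00") & (t["condition"] == "KT"))]
        with pytest.warns(UserWarning):
            f, df1, df2, _ = rm_anova(t, "ch", "m")
        assert df2 == 2 * 3  # 4 complete subjects

    def test_too_few_subjects_rejected(self):
        y = np.random.default_rng(1).random((2, 3))
        with pytest.raises(ValueError):
            rm_anova(make_table(y), "ch", "m")


class TestTukey:
    def test_identical_condition_means_p_near_one(self):
        subj = np.random.default_rng(2).standard_normal(6)
        y = subj[:, None] + np.array([1.0, 1.0, 1.0])
        noise = np.random.default_rng(3).standard_normal((6, 3)) * 0.2
        y = y + noise - noise.mean(axis=0)  # exact equal means, nonzero error
        ps = tukey_posthoc(make_table(y), "ch", "m")
        assert all(p > 0.999 for p in ps.values())

    def test_matches_integrated_studentized_range(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((6, 3)) + np.array([0.0, 0.6, 1.1])
        table = make_table(y)
        ps = tukey_posthoc(table, "ch", "m")
        # re-derive q statistics with plain arithmetic
        n, c = y.shape
        grand = y.mean()
        ss_err = ((y - grand) ** 2).sum() - c * ((y.mean(1) - grand) ** 2).sum() - n * (
            (y.mean(0) - grand) ** 2
        ).sum()
        ms_err = ss_err / ((c - 1) * (n - 1))
        conds = ["NT", "ST", "KT"]
        for (a, b), p in ps.items():
            i, j = conds.index(a), conds.index(b)
            q = abs(y[:, i].mean() - y[:, j].mean()) / np.sqrt(ms_err / n)
            oracle = studentized_range_sf_integrated(q, c, (c - 1) * (n - 1))
            assert p == pytest.approx(oracle, abs=1e-6)

    def test_adjusted_p_dominates_pairwise_t(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.standard_normal((5, 3)) + rng.standard_normal(3)
            table = make_table(y)
            ps = tukey_posthoc(table, "ch", "m")
            n, c = y.shape
            grand = y.mean()
            ss_err = ((y - grand) ** 2).sum() - c * ((y.mean(1) - grand) ** 2).sum() - n * (
                (y.mean(0) - grand) ** 2
            ).sum()
            ms_err = ss_err / ((c - 1) * (n - 1))
            conds = ["NT", "ST", "KT"]
            for (a, b), p in ps.items():
                i, j = conds.index(a), conds.index(b)
                tstat = abs(y[:, i].mean() - y[:, j].mean()) / np.sqrt(2 * ms_err / n)
                p_t = 2 * sst.t.sf(tstat, (c - 1) * (n - 1))
                assert p >= p_t - 1e-12


class TestCompareConditions:
    def test_full_comparison_structure(self, toy_table):
        table, _ = toy_table
        out = compare_conditions(table)
        assert len(out) == 1
        c = out[0]
        assert c.conditions == ("NT", "ST", "KT")
        assert set(c.tukey) == {("NT", "ST"), ("NT", "KT"), ("ST", "KT")}
        assert c.df1 == 2 and c.df2 == 8
        assert 0.0 <= c.p_anova <= 1.0

    def test_posthoc_skippable(self, toy_table):
        table, _ = toy_table
        assert compare_conditions(table, posthoc=False)[0].tukey == {}

    def test_condition_order_helper(self):
        assert condition_order(["KT", "ST", "NT"]) == ["NT", "ST", "KT"]
        assert condition_order(["B", "NT", "A"]) == ["NT", "B", "A"]
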