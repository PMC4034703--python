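import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vfgn.analysis import (
    age_correlation,
    mixed_anova,
    one_sample_t,
    paired_t,
    pairwise_group_tests,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# brute-force projection oracle for the split-plot decomposition
# ---------------------------------------------------------------------------

def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def projection_anova(table, dv, subject="subject", between="group", within="block"):
    """Sequential sums of squares via nested least-squares model fits."""
    df = table.reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)

    def dummies(*cols):
        key = df[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(dtype=float)

    n = len(df)
    X0 = np.ones((n, 1))
    Xg = np.hstack([X0, dummies(between)])
    Xs = np.hstack([X0, dummies(subject)])            # subjects nest groups
    Xsb = np.hstack([Xs, dummies(within)])
    Xsbg = np.hstack([Xs, dummies(within), dummies(between, within)])
    rss = [_rss(y, X) for X in (X0, Xg, Xs, Xsb, Xsbg)]
    return {
        "group": rss[0] - rss[1],
        "subjects(within groups)": rss[1] - rss[2],
        "block": rss[2] - rss[3],
        "block*group": rss[3] - rss[4],
        "block*subjects(within groups)": rss[4],
    }


def make_table(n_groups, n_subjects, n_blocks, rng, group_shift=0.0):
    rows = []
    sid = 0
    for g in range(n_groups):
        for s in range(n_subjects):
            sid += 1
            subj_eff = rng.normal(0, 1.0)
            for b in range(n_blocks):
                rows.append(
                    {
                        "subject": f"s{sid}",
                        "group": f"g{g}",
                        "block": b + 1,
                        "y": g * group_shift + subj_eff - 0.4 * b + rng.normal(0, 0.8),
                    }
                )
    return pd.DataFrame(rows)


class TestOneSampleT:
    def test_symmetric_about_mu0(self):
        res = one_sample_t([0.25, 0.25, 0.26, 0.24], 0.25)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed(self):
        # mean 3, sd 1.5811, n 5: t = 3 / (1.5811/2.2361) = 4.2426
        res = one_sample_t([1, 2, 3, 4, 5], 0.0)
        assert res.t == pytest.approx(3.0 / (math.sqrt(2.5) / math.sqrt(5)), rel=1e-12)
        assert res.t == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4

    def test_matches_scipy(self, rng):
        v = rng.normal(0.3, 1.0, size=25)
        res = one_sample_t(v, 0.1)
        ref = stats.ttest_1samp(v, 0.1)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning):
            res = one_sample_t([2.0, 2.0, 2.0], 1.0)
        assert res.p == 0.0 and res.degenerate
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0], 2.0)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_hand_computed_pooled(self):
        # pooled sd 1.0, se = sqrt(2/3): t = -3/se = -3.674, df 4
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    @pytest.mark.parametrize("pooled", [True, False])
    def test_matches_scipy(self, rng, pooled):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1.6, 14)
        res = two_sample_t(a, b, pooled=pooled)
        ref = stats.ttest_ind(a, b, equal_var=pooled)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_paired_unpaired_reduction(self, rng):
        """paired_t equals the one-sample t of differences, by identity."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.3, 1, 12)
        pr = paired_t(a, b)
        os = one_sample_t(a - b, 0.0)
        assert (pr.t, pr.df, pr.p) == (os.t, os.df, os.p)
        ref = stats.ttest_rel(a, b)
        assert pr.t == pytest.approx(ref.statistic, rel=1e-12)


class TestMixedAnova:
    def test_all_constant_reports_zero(self):
        table = make_table(2, 3, 2, np.random.default_rng(0))
        table["y"] = 5.0
        with pytest.warns(UserWarning):
            res = mixed_anova(table, "y")
        assert (res.table["SS"] == 0).all()
        assert (res.table["F"].dropna() == 0).all()
        assert res.degenerate

    @pytest.mark.parametrize(
        "n_groups,n_subjects,n_blocks",
        list(itertools.product([2, 3], [2, 3, 4], [2, 3, 4])),
    )
    def test_matches_projection_oracle(self, n_groups, n_subjects, n_blocks):
        rng = np.random.default_rng(n_groups * 100 + n_subjects * 10 + n_blocks)
        table = make_table(n_groups, n_subjects, n_blocks, rng, group_shift=0.7)
        res = mixed_anova(table, "y").table.set_index("effect")
        oracle = projection_anova(table, "y")
        for effect, ss in oracle.items():
            assert res.loc[effect, "SS"] == pytest.approx(ss, abs=1e-8), effect

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        table = make_table(2, 8, 4, np.random.default_rng(3), group_shift=0.5)
        mine = mixed_anova(table, "y").table.set_index("effect")
        ref = pg.mixed_anova(
            data=table, dv="y", within="block", subject="subject", between="group"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine.loc["block", "F"] == pytest.approx(ref.loc["block", "F"], rel=1e-9)
        assert mine.loc["block*group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine.loc["group", "p"] == pytest.approx(ref.loc["group", "p_unc"], rel=1e-9)

    def test_shift_invariance_and_additivity(self):
        rng = np.random.default_rng(12)
        table = make_table(2, 5, 3, rng, group_shift=1.0)
        base = mixed_anova(table, "y").table
        shifted = table.copy()
        shifted["y"] += 100.0
        after = mixed_anova(shifted, "y").table
        assert np.allclose(base["SS"], after["SS"], rtol=1e-9, atol=1e-9)
        y = table["y"].to_numpy()
        ss_total = float(np.sum((y - y.mean()) ** 2))
        assert base["SS"].sum() == pytest.approx(ss_total, rel=1e-9)
        # degrees of freedom partition N*B - 1
        assert base["df"].sum() == len(table) - 1

    def test_unbalanced_names_offender(self):
        table = make_table(2, 3, 3, np.random.default_rng(5))
        table = table[~((table["subject"] == "s2") & (table["block"] == 3))]
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(table, "y")

    def test_two_between_factors(self):
        rng = np.random.default_rng(8)
        rows = []
        sid = 0
        for g in ("hc", "sz"):
            for sex in ("M", "F"):
                for _ in range(4):
                    sid += 1
                    eff = rng.normal(0, 1)
                    for b in range(3):
                        rows.append(
                            {
                                "subject": f"s{sid}",
                                "group": g,
                                "sex": sex,
                                "block": b,
                                "y": eff + (g == "sz") * 2.0 + rng.normal(0, 0.5),
                            }
                        )
        table = pd.DataFrame(rows)
        res = mixed_anova(table, "y", second_between="sex")
        effects = set(res.table["effect"])
        assert {"group", "sex", "group*sex", "block", "block*group"} <= effects
        # SS still partition the total
        y = table["y"].to_numpy()
        assert res.table["SS"].sum() == pytest.approx(
            float(np.sum((y - y.mean()) ** 2)), rel=1e-9
        )
        # group effect should be detectable
        assert res.p("group") < 0.05


class TestAgeCorrelation:
    @staticmethod
    def table_from(values, ages, group="g"):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(len(values))],
                "group": group,
                "age": ages,
                "m": values,
            }
        )

    def test_metric_identical_to_age(self):
        ages = np.arange(20.0, 35.0)
        res = age_correlation(self.table_from(ages, ages), "m")
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        ages = rng.uniform(18, 35, 29)
        vals = 0.3 * ages + rng.normal(0, 2, 29)
        res = age_correlation(self.table_from(vals, ages), "m")
        ref = stats.pearsonr(ages, vals)
        assert res["r"].iloc[0] == pytest.approx(ref.statistic, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_one_error_rate(self):
        """|r| exceeds the 5% critical value in about 5% of null replicates."""
        rng = np.random.default_rng(99)
        n, reps = 29, 1000
        crit = stats.t.ppf(0.975, n - 2)
        hits = 0
        for _ in range(reps):
            ages = rng.uniform(18, 35, n)
            vals = rng.normal(0, 1, n)
            r = np.corrcoef(ages, vals)[0, 1]
            t = r * math.sqrt((n - 2) / (1 - r * r))
            hits += abs(t) > crit
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError):
            age_correlation(self.table_from(np.ones(10), np.arange(10.0) + 20), "m")

    def test_age_sensitive_cohort_shows_negative_path_correlation(self):
        """Agents whose memory noise grows with age navigate less efficiently."""
        from vfgn.agents import load_preset, make_cohort
        from vfgn.pipeline import simulate_rm_cohort

        preset = load_preset("healthy_like")
        preset = {**preset, "age_slope_memory_sd0": 0.9}
        cohort = make_cohort({"hc": preset}, 29, 71)
        _, blocks = simulate_rm_cohort(cohort, 72)
        res = age_correlation(blocks, "path_efficiency")
        assert res["r"].iloc[0] < 0


def test_pairwise_holm_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    table = pd.DataFrame(
        {
            "group": np.repeat(["a", "b", "c"], 15),
            "y": np.concatenate(
                [rng.normal(0, 1, 15), rng.normal(0.8, 1, 15), rng.normal(0.1, 1, 15)]
            ),
        }
    )
    res = pairwise_group_tests(table, "y")
    adj = multipletests(res["p"], method="holm")[1]
    assert np.allclose(res["p_holm"], adj)
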