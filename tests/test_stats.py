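"""Normality gating, paired dispatch, RM/mixed ANOVA, Pearson correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from wearadhere.stats import (
    GAUSSIAN,
    NON_GAUSSIAN,
    PairedSample,
    mixed_anova,
    normality_gate,
    paired_compare,
    pearson_r,
    rm_anova,
)


class TestNormalityGate:
    def test_normal_samples_pass_most_of_the_time(self):
        rng = np.random.default_rng(0)
        passed = sum(
            bool(normality_gate(rng.normal(size=200))) for _ in range(100)
        )
        assert passed >= 90

    def test_heavy_tails_fail_most_of_the_time(self):
        rng = np.random.default_rng(1)
        failed = sum(
            not normality_gate(rng.standard_t(2, size=200)) for _ in range(100)
        )
        assert failed >= 90

    def test_below_validity_floor_routes_nonparametric(self):
        result = normality_gate([1.0, 2.0, 3.0, 4.0, 5.0])
        assert result.label == NON_GAUSSIAN
        assert any("floor" in f for f in result.flags)

    def test_constant_vector_flagged(self):
        result = normality_gate([3.0] * 20)
        assert result.label == NON_GAUSSIAN
        assert "zero variance" in result.flags


def _ese_like_differences(n=10, mean=9.01, sd=10.47, seed=4):
    """A Gaussian-looking n=10 vector rescaled to an exact mean and SD."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPairedCompare:
    def test_identical_samples_give_null_result(self):
        values = tuple(float(v) for v in range(3, 13))
        sample = PairedSample(
            ids=tuple(f"s{i}" for i in range(10)), values_a=values, values_b=values
        )
        res = paired_compare(sample)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 9.0

    def test_self_efficacy_style_decline(self):
        """n=10 paired differences with mean 9.01 and SD 10.47 give
        t(9) = 2.72 and a 95% CI of (1.52, 16.50) on the mean difference —
        the arithmetic of a questionnaire-score decline in a 10-person
        cohort."""
        d = _ese_like_differences()
        a = tuple(np.zeros(10))
        sample = PairedSample(
            ids=tuple(f"s{i}" for i in range(10)), values_a=a, values_b=tuple(d)
        )
        res = paired_compare(sample)
        assert res.test_name == "paired_t"
        assert res.statistic == pytest.approx(2.72, abs=0.01)
        assert res.df == 9.0
        assert res.mean_difference == pytest.approx(9.01)
        assert res.ci95[0] == pytest.approx(1.52, abs=0.01)
        assert res.ci95[1] == pytest.approx(16.50, abs=0.01)

    def test_skewed_differences_route_to_wilcoxon(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=40)
        b = a + rng.exponential(2.0, size=40) ** 2  # strongly skewed shifts
        sample = PairedSample(
            ids=tuple(f"s{i}" for i in range(40)),
            values_a=tuple(a),
            values_b=tuple(b),
        )
        res = paired_compare(sample)
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.direction == 1

    def test_shift_invariance_of_t(self):
        d = _ese_like_differences()
        base = paired_compare(
            PairedSample(tuple(map(str, range(10))), tuple(np.zeros(10)), tuple(d))
        )
        shifted = paired_compare(
            PairedSample(tuple(map(str, range(10))), tuple(np.full(10, 7.0)), tuple(d + 7.0))
        )
        assert shifted.statistic == pytest.approx(base.statistic)
        assert shifted.p_value == pytest.approx(base.p_value)


def long_format(values: np.ndarray, times, group=None):
    """values: (n_subjects, n_times) array -> long table."""
    rows = []
    for i, row in enumerate(values):
        for j, t in enumerate(times):
            rec = {"id": f"s{i}", "time": t, "value": float(row[j])}
            if group is not None:
                rec["group"] = group[i]
            rows.append(rec)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_no_within_subject_change(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        data = long_format(np.column_stack([base, base, base]), ["t1", "t2", "t3"])
        res = rm_anova(data)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_levels_equal_paired_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=14), rng.normal(0.6, 1.0, size=14)
        data = long_format(np.column_stack([a, b]), ["pre", "post"])
        res = rm_anova(data)
        t, _ = st.ttest_rel(b, a)
        assert res.statistic == pytest.approx(t**2, rel=1e-6)

    def test_greenhouse_geisser_applied_on_sphericity_violation(self):
        """Strongly unequal difference variances trigger Mauchly, and the
        corrected df shrink by the epsilon factor."""
        rng = np.random.default_rng(4)
        n = 24
        s = rng.normal(size=n)
        values = np.column_stack(
            [s + rng.normal(0, 0.05, n), s + rng.normal(0, 0.05, n), s + rng.normal(0, 3.0, n)]
        )
        res = rm_anova(long_format(values, ["t1", "t2", "t3"]))
        assert res.test_name == "rm_anova"
        assert res.correction_applied
        df1, df2 = res.df
        assert df1 < 2.0 and df2 < 2.0 * (n - 1)

    def test_non_gaussian_cell_routes_to_friedman(self):
        rng = np.random.default_rng(3)
        n = 20
        values = np.column_stack(
            [rng.normal(size=n), rng.normal(size=n), rng.standard_cauchy(size=n)]
        )
        res = rm_anova(long_format(values, ["t1", "t2", "t3"]))
        assert res.test_name == "friedman"

    def test_friedman_and_rm_anova_agree_on_strong_signal(self):
        """On clearly signalled data both routes reject, whatever the gate
        would have picked (dispatch consistency, 20 seeded replicates)."""
        agreements = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 30
            base = rng.normal(size=n)
            values = np.column_stack([base, base + 2.0 + rng.normal(0, 1, n),
                                      base + 4.0 + rng.normal(0, 1, n)])
            frame = long_format(values, ["t1", "t2", "t3"])
            res = rm_anova(frame)
            wide = frame.pivot(index="id", columns="time", values="value")
            f_stat, f_p = st.friedmanchisquare(wide["t1"], wide["t2"], wide["t3"])
            agreements += (res.p_value < 0.05) == (f_p < 0.05)
        assert agreements >= 19

    def test_insufficient_cases_rejected(self):
        data = long_format(np.array([[1.0, 2.0]]), ["t1", "t2"])
        with pytest.raises(ValueError):
            rm_anova(data)


class TestMixedAnova:
    def test_no_time_change_in_either_group_kills_interaction(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=16)
        group = ["g1"] * 8 + ["g2"] * 8
        data = long_format(np.column_stack([base, base]), ["pre", "post"], group)
        res = mixed_anova(data)
        assert res.interaction.statistic == pytest.approx(0.0, abs=1e-10)

    def test_interaction_equals_t_squared_on_difference_scores(self):
        rng = np.random.default_rng(1)
        n = 20
        pre, post = rng.normal(size=n), rng.normal(size=n)
        group = ["g1"] * 10 + ["g2"] * 10
        res = mixed_anova(long_format(np.column_stack([pre, post]), ["pre", "post"], group))
        d = post - pre
        t, p = st.ttest_ind(d[:10], d[10:])
        assert res.interaction.statistic == pytest.approx(t**2, rel=1e-9)
        assert res.interaction.p_value == pytest.approx(p, rel=1e-9)

    def test_decline_confined_to_one_group_mirrors_cohort_analysis(self):
        """A 4-vs-6 split where only the slower group declines yields a
        significant interaction and a significant within-slower time
        effect — the shape of the walk-test subgroup analysis."""
        rng = np.random.default_rng(2)
        pre = np.concatenate([rng.normal(570, 15, 4), rng.normal(465, 15, 6)])
        change = np.concatenate([rng.normal(2, 8, 4), rng.normal(-35, 8, 6)])
        group = ["faster"] * 4 + ["slower"] * 6
        res = mixed_anova(
            long_format(np.column_stack([pre, pre + change]), ["pre", "post"], group),
        )
        assert res.interaction.significant
        assert res.interaction.df == (1.0, 8.0)
        within_slower = next(
            e for e in res.simple_effects if e.label == "time_within_slower"
        )
        assert within_slower.significant
        between = [e for e in res.simple_effects if "@" in e.label]
        assert len(between) == 2  # one per time point

    def test_welch_correction_on_unequal_variances(self):
        """A between-group follow-up on strongly unequal variances uses the
        Welch t with fractional df."""
        rng = np.random.default_rng(8)
        pre = np.concatenate([rng.normal(500, 2, 8), rng.normal(460, 60, 8)])
        change = np.concatenate([np.full(8, 1.0) + rng.normal(0, 1, 8),
                                 np.full(8, -45.0) + rng.normal(0, 12, 8)])
        group = ["g1"] * 8 + ["g2"] * 8
        res = mixed_anova(
            long_format(np.column_stack([pre, pre + change]), ["pre", "post"], group),
            followups="always",
        )
        welch = [e for e in res.simple_effects if e.test_name == "welch_t"]
        assert welch, "expected at least one Welch-corrected follow-up"
        assert any(abs(e.df - round(e.df)) > 1e-6 for e in welch)

    def test_single_member_group_rejected(self):
        data = long_format(
            np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 2.0]]),
            ["pre", "post"],
            ["g1", "g2", "g2"],
        )
        with pytest.raises(ValueError):
            mixed_anova(data)


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, -x)
        assert res.statistic == pytest.approx(-1.0)
        assert res.direction == -1

    def test_r067_n7_p_value_by_brute_force(self):
        """r = 0.67 at n = 7: the exact t-transform gives a two-tailed p of
        ~0.0997; the printed one-tailed value sits at ~0.0499. Both are
        recovered by direct evaluation."""
        r, n = 0.67, 7
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p_two = 2 * st.t.sf(t, n - 2)
        assert p_two == pytest.approx(0.0997, abs=0.0005)
        assert p_two / 2 == pytest.approx(0.049, abs=0.001)
        # the library path agrees with the brute-force transform
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=7), rng.normal(size=7)
            res = pearson_r(x, y)
            tt = res.statistic * np.sqrt(5) / np.sqrt(1 - res.statistic**2)
            assert res.p_value == pytest.approx(2 * st.t.sf(abs(tt), 5), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0, 3.0])
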