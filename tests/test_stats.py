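"""ICC(3,1), the 2 x 2 within-subject ANOVA and the post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftforce import (
    InsufficientDataError,
    InvalidArgumentError,
    PairedAgreement,
    TwoWayRepeatedAnova,
    UndefinedStatisticError,
    cohens_d,
    icc_3_1,
    interpret_icc,
    rm_anova_2x2,
    switch_contrasts,
)


def naive_rm_anova(y):
    """Independent sum-of-squares oracle: explicit loops, long-hand means."""
    n = len(y)
    grand = sum(y[i][a][b] for i in range(n) for a in range(2) for b in range(2)) / (
        4 * n
    )
    subj = [sum(y[i][a][b] for a in range(2) for b in range(2)) / 4 for i in range(n)]
    a_m = [sum(y[i][a][b] for i in range(n) for b in range(2)) / (2 * n) for a in range(2)]
    b_m = [sum(y[i][a][b] for i in range(n) for a in range(2)) / (2 * n) for b in range(2)]
    ab_m = [
        [sum(y[i][a][b] for i in range(n)) / n for b in range(2)] for a in range(2)
    ]
    sa = [[sum(y[i][a][b] for b in range(2)) / 2 for a in range(2)] for i in range(n)]
    sb = [[sum(y[i][a][b] for a in range(2)) / 2 for b in range(2)] for i in range(n)]
    ss_a = 2 * n * sum((m - grand) ** 2 for m in a_m)
    ss_b = 2 * n * sum((m - grand) ** 2 for m in b_m)
    ss_ab = n * sum(
        (ab_m[a][b] - a_m[a] - b_m[b] + grand) ** 2 for a in range(2) for b in range(2)
    )
    ss_as = 2 * sum(
        (sa[i][a] - subj[i] - a_m[a] + grand) ** 2 for i in range(n) for a in range(2)
    )
    ss_bs = 2 * sum(
        (sb[i][b] - subj[i] - b_m[b] + grand) ** 2 for i in range(n) for b in range(2)
    )
    ss_abs = sum(
        (
            y[i][a][b]
            - sa[i][a]
            - sb[i][b]
            - ab_m[a][b]
            + subj[i]
            + a_m[a]
            + b_m[b]
            - grand
        )
        ** 2
        for i in range(n)
        for a in range(2)
        for b in range(2)
    )
    import scipy.stats

    out = {}
    for name, ss_eff, ss_err in (
        ("cube", ss_a, ss_as),
        ("switch", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        F = ss_eff / (ss_err / (n - 1))
        out[name] = {
            "F": F,
            "p": scipy.stats.f.sf(F, 1, n - 1),
            "np2": ss_eff / (ss_eff + ss_err),
        }
    return out


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_3_1(x).estimate == pytest.approx(1.0)

    def test_additive_offset_is_ignored_by_the_consistency_form(self):
        col = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 3.0])
        res = icc_3_1(np.column_stack([col, col + 2.5]))
        assert res.estimate == pytest.approx(1.0)

    def test_matches_an_independent_anova_assembly(self, rng):
        row = rng.normal(0, 2, 6)
        x = np.column_stack(
            [row + rng.normal(0, 0.5, 6), row + rng.normal(0, 0.5, 6)]
        )
        res = icc_3_1(x)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 2),
                "method": np.tile(["a", "b"], 6),
                "score": x.ravel(),
            }
        )
        tab = sm.stats.anova_lm(
            ols("score ~ C(subject) + C(method)", data=long).fit(), typ=2
        )
        msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
        mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
        assert res.estimate == pytest.approx((msr - mse) / (msr + mse), abs=1e-10)

    def test_matches_pingouin_estimate_and_interval(self, rng):
        row = rng.normal(0, 2, 12)
        x = np.column_stack(
            [row + rng.normal(0, 0.7, 12), 1.3 + row + rng.normal(0, 0.7, 12)]
        )
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": x.ravel(),
            }
        )
        table = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        for form, label in (("consistency", "ICC(C,1)"), ("absolute", "ICC(A,1)")):
            res = icc_3_1(x, form=form)
            assert res.estimate == pytest.approx(table.loc[label, "ICC"], abs=1e-9)
            lo, hi = table.loc[label, "CI95"]
            assert res.ci_low == pytest.approx(lo, abs=0.005)
            assert res.ci_high == pytest.approx(hi, abs=0.005)

    def test_row_permutation_and_column_offset_invariance(self, rng):
        row = rng.normal(0, 1, 10)
        x = np.column_stack([row + rng.normal(0, 0.3, 10), row + rng.normal(0, 0.3, 10)])
        base = icc_3_1(x).estimate
        assert icc_3_1(x + np.array([0.0, 17.0])).estimate == pytest.approx(base)
        perm = rng.permutation(10)
        assert icc_3_1(x[perm]).estimate == pytest.approx(base)

    def test_too_few_pairs_and_zero_variance_raise(self):
        with pytest.raises(InsufficientDataError):
            icc_3_1(np.ones((4, 2)))
        with pytest.raises(UndefinedStatisticError):
            icc_3_1(np.ones((6, 2)))

    def test_rows_with_missing_values_are_dropped_first(self, rng):
        row = rng.normal(0, 1, 8)
        x = np.column_stack([row, row + rng.normal(0, 0.1, 8)])
        x_with_nan = np.vstack([x, [np.nan, 1.0]])
        assert PairedAgreement(x_with_nan).fit().estimate == pytest.approx(
            icc_3_1(x).estimate
        )


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value, band",
        [(0.49, "poor"), (0.6, "moderate"), (0.87, "good"), (0.98, "excellent")],
    )
    def test_conventional_bands(self, value, band):
        assert interpret_icc(value) == band

    def test_overlapping_boundaries_default_to_the_lower_band(self):
        assert interpret_icc(0.50) == "poor"
        assert interpret_icc(0.75) == "moderate"
        assert interpret_icc(0.90) == "good"

    def test_upper_boundary_mode_is_available(self):
        assert interpret_icc(0.75, boundary="upper") == "good"


class TestRmAnova:
    def test_identical_cells_everywhere_is_degenerate_not_a_crash(self):
        res = rm_anova_2x2(np.ones((6, 2, 2)))
        assert all(e.degenerate for e in res.effects.values())

    def test_pure_interaction_pattern_loads_only_the_interaction(self, rng):
        pattern = np.array([[1.0, -1.0], [-1.0, 1.0]])
        y = pattern[None] + rng.normal(0, 0.01, (10, 2, 2))
        res = rm_anova_2x2(y)
        assert res.effects["interaction"].F > 1e3
        assert res.effects["cube"].F < 10
        assert res.effects["switch"].F < 10

    def test_matches_the_naive_loop_oracle_to_6_decimals(self, rng):
        y = rng.normal(0, 1, (8, 2, 2)) + rng.normal(0, 1, (8, 1, 1))
        res = rm_anova_2x2(y)
        oracle = naive_rm_anova(y.tolist())
        for name in ("cube", "switch", "interaction"):
            assert res.effects[name].F == pytest.approx(oracle[name]["F"], abs=1e-6)
            assert res.effects[name].p == pytest.approx(oracle[name]["p"], abs=1e-6)
            assert res.effects[name].partial_eta_sq == pytest.approx(
                oracle[name]["np2"], abs=1e-6
            )

    def test_matches_pingouin_f_and_p(self, rng):
        y = rng.normal(0, 1, (9, 2, 2))
        import pingouin as pg

        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(9), 4),
                "cube": np.tile(np.repeat(["light", "heavy"], 2), 9),
                "switch": np.tile(["no_switch", "switch"], 18),
                "value": y.reshape(-1),
            }
        )
        table = pg.rm_anova(
            data=df, dv="value", within=["cube", "switch"], subject="subject"
        ).set_index("Source")
        res = rm_anova_2x2(y)
        for mine, theirs in (
            ("cube", "cube"),
            ("switch", "switch"),
            ("interaction", "cube * switch"),
        ):
            assert res.effects[mine].F == pytest.approx(table.loc[theirs, "F"], abs=1e-8)
            assert res.effects[mine].p == pytest.approx(
                table.loc[theirs, "p_unc"], abs=1e-8
            )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_f_equals_t_squared_for_every_effect(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, (7, 2, 2))
        res = rm_anova_2x2(y)
        import scipy.stats

        contrasts = {
            "cube": y[:, 1, :].mean(axis=1) - y[:, 0, :].mean(axis=1),
            "switch": y[:, :, 1].mean(axis=1) - y[:, :, 0].mean(axis=1),
            "interaction": (y[:, 1, 1] - y[:, 1, 0]) - (y[:, 0, 1] - y[:, 0, 0]),
        }
        for name, c in contrasts.items():
            t, _ = scipy.stats.ttest_1samp(c, 0.0)
            assert res.effects[name].F == pytest.approx(t**2, rel=1e-9)

    def test_from_dataframe_drops_incomplete_participants(self, rng):
        y = rng.normal(0, 1, (6, 2, 2))
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(6), 4),
                "cube": np.tile(np.repeat(["light", "heavy"], 2), 6),
                "switch": np.tile(["no_switch", "switch"], 12),
                "value": y.reshape(-1),
            }
        )
        df.loc[0, "value"] = np.nan  # participant 0 loses one cell
        model = TwoWayRepeatedAnova.from_dataframe(df)
        assert model.n_dropped == 1
        assert model.fit().n == 5


class TestContrastsAndEffectSizes:
    def test_identical_columns_give_zero_difference_and_p_one(self, rng):
        y = rng.normal(0, 1, (8, 2, 1)).repeat(2, axis=2)
        for c in switch_contrasts(y):
            assert c.mean_difference == pytest.approx(0.0)
            assert c.p_bonferroni == pytest.approx(1.0)

    def test_constant_shift_without_noise_is_flagged_degenerate(self, rng):
        y = rng.normal(0, 1, (8, 2, 1)).repeat(2, axis=2)
        y[:, :, 1] += 0.7
        for c in switch_contrasts(y):
            assert c.degenerate

    def test_matches_a_textbook_paired_t_computation(self, rng):
        y = rng.normal(0, 1, (29, 2, 2))
        y[:, 1, 1] += 0.5  # heavy/switch bump: an injected interaction
        results = {c.cube: c for c in switch_contrasts(y)}
        for i, cube in enumerate(("light", "heavy")):
            diffs = y[:, i, 1] - y[:, i, 0]
            t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(29))
            import scipy.stats

            p_oracle = 2 * scipy.stats.t.sf(abs(t_oracle), 28)
            c = results[cube]
            assert c.t == pytest.approx(t_oracle, abs=1e-9)
            assert c.p_bonferroni == pytest.approx(min(1.0, 2 * p_oracle), abs=1e-9)
            assert c.cohens_d == pytest.approx(diffs.mean() / diffs.std(ddof=1))

    def test_cohens_d_trivial_cases(self):
        assert cohens_d(np.array([2.0, 2.0, 2.0])).degenerate
        assert cohens_d(np.array([-1.0, 0.0, 1.0])).value == pytest.approx(0.0)

    def test_both_d_variants_match_the_direct_formulas(self, rng):
        a = rng.normal(1.0, 1.0, 20)
        b = rng.normal(0.0, 2.0, 20)
        dz = cohens_d(a, b, variant="dz")
        dav = cohens_d(a, b, variant="dav")
        diffs = a - b
        assert dz.value == pytest.approx(diffs.mean() / diffs.std(ddof=1))
        assert dav.value == pytest.approx(
            diffs.mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
        )
        with pytest.raises(InvalidArgumentError):
            cohens_d(diffs, variant="dav")
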