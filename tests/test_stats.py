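import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loombias.stats import (
    DesignError,
    average_cells,
    cohens_d,
    convert_to_mps,
    exclude_speed_of_sound,
    gg_epsilon,
    independent_t,
    mixed_anova,
    paired_t,
    partial_eta_sq_from_f,
    rm_anova,
    tukey_hsd,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def projection_ss(A, axes):
    """Balanced-ANOVA SS via explicit Kronecker projection matrices.

    Independent of the marginal-means route: builds the orthogonal projector
    onto the effect subspace (centering matrices for axes in the effect,
    averaging matrices elsewhere) and evaluates the quadratic form directly.
    """
    mats = []
    for a in range(A.ndim):
        k = A.shape[a]
        J = np.full((k, k), 1.0 / k)
        mats.append(np.eye(k) - J if a in axes else J)
    P = mats[0]
    for M in mats[1:]:
        P = np.kron(P, M)
    y = A.reshape(-1)
    return float(y @ P @ y)


def frame_from_array(A, factor_names):
    """Long-format DataFrame from a (n_subjects, k1, ..., km) array."""
    n = A.shape[0]
    rows = []
    for idx in np.ndindex(*A.shape):
        rows.append([f"s{idx[0]}", *[f"l{j}" for j in idx[1:]], A[idx]])
    return pd.DataFrame(rows, columns=["participant_id", *factor_names,
                                       "estimate_mps"])


# ---------------------------------------------------------------------------
# conversion, exclusion, averaging
# ---------------------------------------------------------------------------

class TestConversion:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [(44.7, "mph", 19.98), (3.6, "kmh", 1.0), (15.0, "mps", 15.0)],
    )
    def test_examples(self, value, unit, expected):
        assert convert_to_mps(value, unit) == pytest.approx(expected, abs=0.005)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown unit"):
            convert_to_mps(10.0, "furlongs")


def _resp(rows):
    return pd.DataFrame(rows, columns=["participant_id", "distance",
                                       "direction", "speed_mps", "side",
                                       "estimate_mps"])


class TestExclusion:
    def test_all_over_600mph_participant_dropped(self):
        mph = 0.44704
        rows = [["a", "close", "looming", 15.0, "left", v * mph]
                for v in (700.0, 750.0, 767.0)]
        rows += [["b", "close", "looming", 15.0, "left", 30.0]]
        kept, excluded = exclude_speed_of_sound(_resp(rows))
        assert excluded == ["a"]
        assert set(kept["participant_id"]) == {"b"}

    def test_mixed_participant_retained_under_all_rule(self):
        mph = 0.44704
        rows = [["a", "close", "looming", 15.0, "left", 700.0 * mph],
                ["a", "close", "looming", 20.0, "left", 30.0]]
        kept, excluded = exclude_speed_of_sound(_resp(rows))
        assert excluded == []
        assert len(kept) == 2

    def test_empty_table_is_vacuous(self):
        empty = _resp([])
        kept, excluded = exclude_speed_of_sound(empty)
        assert kept.empty and excluded == []

    @given(st.lists(st.floats(min_value=0.1, max_value=400.0), min_size=1,
                    max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_threshold_predicate(self, values):
        rows = [["a", "close", "looming", 15.0, "left", v] for v in values]
        kept, excluded = exclude_speed_of_sound(_resp(rows))
        should_drop = all(v > 600 * 0.44704 for v in values)
        assert (excluded == ["a"]) == should_drop


class TestAverageCells:
    def test_two_side_trials_average(self):
        rows = [["a", "close", "looming", 15.0, "left", 10.0],
                ["a", "close", "looming", 15.0, "right", 20.0]]
        cells = average_cells(_resp(rows))
        assert len(cells) == 1
        assert cells["estimate_mps"].iloc[0] == pytest.approx(15.0)

    def test_full_table_yields_n_by_12(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in "abc":
            for d in ("close", "distant"):
                for g in ("looming", "receding"):
                    for v in (15.0, 20.0, 25.0):
                        for s in ("left", "right"):
                            rows.append([pid, d, g, v, s, rng.uniform(5, 50)])
        cells = average_cells(_resp(rows))
        assert len(cells) == 3 * 12

    def test_idempotent_on_averaged_table(self):
        rows = [["a", "close", "looming", 15.0, "left", 10.0],
                ["a", "close", "looming", 15.0, "right", 20.0],
                ["a", "close", "looming", 20.0, "left", 12.0],
                ["a", "close", "looming", 20.0, "right", 14.0]]
        once = average_cells(_resp(rows))
        twice = average_cells(once)  # one value per cell now; no-op
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_missing_side_warns_and_keeps_lone_value(self):
        rows = [["a", "close", "looming", 15.0, "left", 10.0],
                ["a", "close", "looming", 15.0, "right", 20.0],
                ["a", "close", "looming", 20.0, "left", 12.0]]  # right missing
        with pytest.warns(UserWarning, match="fewer trials"):
            cells = average_cells(_resp(rows))
        by_speed = cells.set_index("speed_mps")["estimate_mps"]
        assert by_speed[20.0] == 12.0
        assert by_speed[15.0] == 15.0

    def test_missing_whole_cell_raises_naming_participant(self):
        rows = [["a", "close", "looming", 15.0, "left", 10.0],
                ["a", "close", "looming", 20.0, "left", 10.0],
                ["b", "close", "looming", 15.0, "left", 10.0]]
        with pytest.raises(DesignError, match="'b'"):
            average_cells(_resp(rows), require_full=True)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    @pytest.mark.parametrize("shape, seed", [
        ((4, 2, 2, 2), 0), ((3, 2, 3), 1), ((5, 3, 2), 2), ((4, 2, 2, 3), 3),
        ((2, 2, 2), 4), ((5, 3), 5),
    ])
    def test_ss_decomposition_matches_projection_oracle(self, shape, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=shape)
        names = [f"f{i}" for i in range(len(shape) - 1)]
        table = rm_anova(frame_from_array(A, names), within=names)
        from itertools import combinations
        factor_axes = range(1, len(shape))
        for r in range(1, len(names) + 1):
            for S in combinations(factor_axes, r):
                name = " x ".join(names[a - 1] for a in S)
                row = table[table["effect"] == name].iloc[0]
                ss_expect = projection_ss(A, S)
                sserr_expect = projection_ss(A, (0, *S))
                assert row["ss"] == pytest.approx(ss_expect, rel=1e-10, abs=1e-12)
                assert row["ms_error"] * row["df2"] == pytest.approx(
                    sserr_expect, rel=1e-10, abs=1e-12)
                assert row["F"] == pytest.approx(
                    (ss_expect / row["df1"]) / (sserr_expect / row["df2"]),
                    rel=1e-10)

    def test_total_ss_partition(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(5, 2, 2, 3))
        names = ["fa", "fb", "fc"]
        table = rm_anova(frame_from_array(A, names), within=names)
        ss_subject = projection_ss(A, (0,))
        total = ((A - A.mean()) ** 2).sum()
        partition = table["ss"].sum() + (
            table["ss"] / table["F"] * table["df2"] / table["df1"]
        ).sum() + ss_subject
        assert partition == pytest.approx(total, rel=1e-8)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        A = rng.normal(size=(6, 2, 2, 3)) + rng.normal(size=(6, 1, 1, 1))
        names = ["fa", "fb", "fc"]
        df = frame_from_array(A, names)
        mine = rm_anova(df, within=names).set_index("effect")
        theirs = AnovaRM(df, "estimate_mps", "participant_id",
                         within=names).fit().anova_table
        for effect, row in theirs.iterrows():
            key = effect.replace(":", " x ")
            assert mine.loc[key, "F"] == pytest.approx(row["F Value"], rel=1e-8)
            assert mine.loc[key, "p"] == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_two_level_factor_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10) + 0.8
        df = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(10)] * 2,
            "cond": ["a"] * 10 + ["b"] * 10,
            "estimate_mps": np.concatenate([x, y]),
        })
        table = rm_anova(df, within=("cond",))
        t, tdf, p = paired_t(x, y)
        assert table["F"].iloc[0] == pytest.approx(t ** 2, rel=1e-10)
        assert table["p"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert table["df2"].iloc[0] == tdf

    def test_eta_identity_for_every_effect(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 2, 3))
        table = rm_anova(frame_from_array(A, ["fa", "fb"]), within=["fa", "fb"])
        for _, row in table.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                partial_eta_sq_from_f(row["F"], row["df1"], row["df2"]),
                rel=1e-10)

    def test_gg_adjusted_p_not_smaller(self):
        rng = np.random.default_rng(10)
        # heteroscedastic levels -> epsilon < 1
        A = rng.normal(size=(8, 3)) * np.array([0.5, 1.0, 3.0])
        table = rm_anova(frame_from_array(A, ["fc"]), within=["fc"])
        row = table.iloc[0]
        assert row["eps_gg"] < 1.0
        assert row["p_gg"] >= row["p"]

    def test_all_equal_data_reports_null_result(self):
        A = np.ones((4, 2, 3)) * 7.0
        table = rm_anova(frame_from_array(A, ["fa", "fb"]), within=["fa", "fb"])
        assert (table["F"] == 0).all()
        assert (table["p"] == 1).all()

    def test_scale_invariance_under_unit_change(self):
        rng = np.random.default_rng(11)
        A = rng.normal(loc=30, scale=8, size=(6, 2, 3))
        names = ["fa", "fb"]
        t1 = rm_anova(frame_from_array(A, names), within=names)
        t2 = rm_anova(frame_from_array(A / 0.44704, names), within=names)
        for col in ("F", "p", "eps_gg", "partial_eta_sq"):
            assert np.allclose(t1[col], t2[col])

    def test_non_crossed_data_rejected(self):
        df = pd.DataFrame({
            "participant_id": ["s0", "s0", "s1"],
            "cond": ["a", "b", "a"],
            "estimate_mps": [1.0, 2.0, 3.0],
        })
        with pytest.raises(DesignError, match="crossed"):
            rm_anova(df, within=("cond",))


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 4
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_two_levels_always_one(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 2)) * [1.0, 5.0]
        assert gg_epsilon(np.cov(X, rowvar=False)) == pytest.approx(1.0)

    def test_rank_one_structure_hits_lower_bound(self):
        # maximally non-spherical: all variance on one centered component
        k = 3
        v = np.array([1.0, 0.0, -1.0])
        S = np.outer(v, v)
        assert gg_epsilon(S) == pytest.approx(1.0 / (k - 1))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            gg_epsilon(np.ones((2, 3)))

    def test_matches_pingouin_epsilon(self):
        import pingouin as pg

        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 3)) * [1.0, 2.0, 4.0]
        mine = gg_epsilon(np.cov(X, rowvar=False))
        theirs = float(pg.epsilon(pd.DataFrame(X), correction="gg"))
        assert mine == pytest.approx(theirs, rel=1e-8)


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _mixed_frame(n_per_cell=6, k=3, seed=0, speed_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for a in ("close", "distant"):
        for b in ("looming", "receding"):
            for _ in range(n_per_cell):
                pid += 1
                base = rng.normal(scale=2) + 1.5 * (a == "close") + \
                    1.0 * (b == "looming")
                for j, v in enumerate((15.0, 20.0, 25.0)[:k]):
                    rows.append([f"p{pid:03d}", a, b, v,
                                 base + speed_effect * j * (b == "looming")
                                 + rng.normal()])
    return pd.DataFrame(rows, columns=["participant_id", "distance",
                                       "direction", "speed_mps",
                                       "estimate_mps"])


class TestMixedAnova:
    def test_between_part_equals_two_way_anova_on_subject_means(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = _mixed_frame(seed=1, speed_effect=0.2)
        mine = mixed_anova(df).set_index("effect")
        means = df.groupby(["participant_id", "distance", "direction"],
                           as_index=False)["estimate_mps"].mean()
        fit = smf.ols("estimate_mps ~ C(distance) * C(direction)",
                      data=means).fit()
        oracle = anova_lm(fit, typ=2)
        pairs = {"distance": "C(distance)", "direction": "C(direction)",
                 "distance x direction": "C(distance):C(direction)"}
        for name, oname in pairs.items():
            assert mine.loc[name, "F"] == pytest.approx(
                oracle.loc[oname, "F"], rel=1e-9)
            assert mine.loc[name, "p"] == pytest.approx(
                oracle.loc[oname, "PR(>F)"], abs=1e-12)

    def test_within_part_matches_pingouin_with_combined_groups(self):
        import pingouin as pg

        df = _mixed_frame(seed=2, speed_effect=0.2)
        mine = mixed_anova(df).set_index("effect")
        df2 = df.assign(group=df["distance"] + "_" + df["direction"])
        theirs = pg.mixed_anova(data=df2, dv="estimate_mps",
                                within="speed_mps", subject="participant_id",
                                between="group").set_index("Source")
        assert mine.loc["speed_mps", "F"] == pytest.approx(
            theirs.loc["speed_mps", "F"], rel=1e-9)
        # our three interaction pieces partition pingouin's group x speed SS
        inter = [n for n in mine.index if n.endswith("x speed_mps")]
        assert mine.loc[inter, "ss"].sum() == pytest.approx(
            theirs.loc["Interaction", "SS"], rel=1e-9)

    def test_brute_force_split_plot_ss(self):
        # naive loop computation of the split-plot decomposition
        df = _mixed_frame(n_per_cell=4, seed=3, speed_effect=0.3)
        mine = mixed_anova(df).set_index("effect")
        piv = df.pivot_table(index=["participant_id", "distance", "direction"],
                             columns="speed_mps", values="estimate_mps")
        Y = piv.to_numpy()
        groups = np.array(["|".join(t) for t in piv.index.droplevel(0)])
        k = Y.shape[1]
        subj = Y.mean(axis=1)
        ss_sw = 0.0
        for g in set(groups):
            m = subj[groups == g]
            ss_sw += k * ((m - m.mean()) ** 2).sum()
        assert mine.loc["distance", "ms_error"] * mine.loc["distance", "df2"] \
            == pytest.approx(ss_sw, rel=1e-9)
        # speed SS from the unweighted group x speed cell means
        cellm = np.array([Y[groups == g].mean(axis=0) for g in sorted(set(groups))])
        n_per = len(subj) // 4
        ss_speed = n_per * 4 * ((cellm.mean(axis=0) - cellm.mean()) ** 2).sum()
        assert mine.loc["speed_mps", "ss"] == pytest.approx(ss_speed, rel=1e-9)

    def test_all_equal_data_reports_null_result(self):
        df = _mixed_frame(seed=4)
        df["estimate_mps"] = 5.0
        table = mixed_anova(df)
        assert (table["F"] == 0).all()
        assert (table["p"] == 1).all()

    def test_participant_in_two_cells_rejected(self):
        df = _mixed_frame(seed=5)
        df.loc[df.index[-3:], "participant_id"] = df["participant_id"].iloc[0]
        with pytest.raises(DesignError):
            mixed_anova(df)

    def test_unbalanced_groups_warn(self):
        df = _mixed_frame(n_per_cell=5, seed=6)
        drop = df["participant_id"] == df["participant_id"].iloc[0]
        with pytest.warns(UserWarning, match="unbalanced"):
            mixed_anova(df[~drop])


# ---------------------------------------------------------------------------
# post hocs, t tests, effect sizes
# ---------------------------------------------------------------------------

class TestTukey:
    def test_two_levels_equal_f_test(self):
        rng = np.random.default_rng(14)
        A = rng.normal(size=(9, 2)) + np.array([0.0, 1.0])
        table = rm_anova(frame_from_array(A, ["fc"]), within=["fc"])
        row = table.iloc[0]
        tk = tukey_hsd(A.mean(axis=0), row["ms_error"], row["df2"], 9)
        # q^2 = 2 F identity at k = 2
        assert tk["q"].iloc[0] ** 2 == pytest.approx(2 * row["F"], rel=1e-9)
        assert tk["p"].iloc[0] == pytest.approx(row["p"], rel=1e-6)

    def test_identical_means_give_p_one(self):
        tk = tukey_hsd([5.0, 5.0, 5.0], ms_error=2.0, df_error=12, n_per_level=5)
        assert np.allclose(tk["p"], 1.0)
        assert not tk["significant"].any()

    def test_matches_monte_carlo_studentized_range(self):
        # three levels; oracle simulates the null studentized range
        means = np.array([0.0, 0.6, 1.1])
        ms, dfe, n = 1.0, 24, 6
        tk = tukey_hsd(means, ms, dfe, n)
        rng = np.random.default_rng(15)
        reps = 400_000
        z = rng.normal(size=(reps, 3))
        s = np.sqrt(rng.chisquare(dfe, size=reps) / dfe)
        q_null = (z.max(axis=1) - z.min(axis=1)) / s
        for _, row in tk.iterrows():
            q_obs = row["q"]
            p_mc = float((q_null > q_obs).mean())
            assert row["p"] == pytest.approx(p_mc, abs=0.005)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd([1.0, 2.0], 1.0, 10, n_per_level=1)


class TestEffectSizesAndT:
    @pytest.mark.parametrize(
        "stats, expected",
        [((45.9, 24.1, 35.2, 21.6), 0.47), ((32.4, 18.6, 29.3, 22.3), 0.15)],
    )
    def test_published_cell_statistics_reproduce_d(self, stats, expected):
        assert round(cohens_d(*stats).d, 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d(10.0, 2.0, 10.0, 3.0).d == 0.0

    def test_scale_invariance(self):
        d1 = cohens_d(45.9, 24.1, 35.2, 21.6).d
        c = 1 / 0.44704
        d2 = cohens_d(45.9 * c, 24.1 * c, 35.2 * c, 21.6 * c).d
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 2.0, 1.0)

    def test_identical_paired_vectors(self):
        t, df, p = paired_t([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert (t, p) == (0.0, 1.0)
        assert df == 2

    def test_paired_t_matches_scipy(self):
        from scipy.stats import ttest_ind, ttest_rel

        rng = np.random.default_rng(16)
        x, y = rng.normal(size=12), rng.normal(size=12) + 0.5
        t, df, p = paired_t(x, y)
        ref = ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        t, df, p = independent_t(x, y)
        ref = ttest_ind(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        t, df, p = independent_t(x, y, pooled=False)
        ref = ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_hand_worked_paired_example(self):
        # differences 2, 4, 6: mean 4, sd 2, t = 4 / (2/sqrt(3)) = 2*sqrt(3)
        t, df, p = paired_t([12.0, 16.0, 20.0], [10.0, 12.0, 14.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert df == 2

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])
        with pytest.raises(ValueError):
            independent_t([1.0], [2.0, 3.0])
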