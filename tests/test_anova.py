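"""Split-plot and factorial ANOVA, post hocs, Bayes factors, RT transform."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lopforget.anova import (
    anova_bayes_factors,
    bayes_factor_bic,
    bonferroni_pairwise,
    factorial_anova,
    kass_raftery_category,
    log_transform_rt,
    mixed_anova,
    tukey_hsd,
)


def _hand_splitplot(df):
    """Textbook balanced split-plot sums of squares, computed directly."""
    wide = df.pivot_table(index=["participant_id", "delay_group"],
                          columns="lop_condition", values="d_prime")
    y = wide.to_numpy(float)
    groups = wide.index.get_level_values("delay_group").to_numpy()
    gnames = sorted(set(groups))
    S, L = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    lev_means = y.mean(axis=0)
    ss_between_subj = L * ((subj_means - grand) ** 2).sum()
    ss_group = L * sum(
        (groups == g).sum() * (subj_means[groups == g].mean() - grand) ** 2
        for g in gnames
    )
    ss_err_b = ss_between_subj - ss_group
    ss_level = S * ((lev_means - grand) ** 2).sum()
    cell_means = np.array([[y[groups == g, l].mean() for l in range(L)] for g in gnames])
    gmeans = np.array([subj_means[groups == g].mean() for g in gnames])
    n_per = len(groups) // len(gnames)
    ss_cells = n_per * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_level
    ss_total = ((y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_level - ss_inter
    return dict(group=ss_group, err_b=ss_err_b, level=ss_level,
                inter=ss_inter, err_w=ss_err_w, total=ss_total)


class TestMixedAnova:
    def test_matches_hand_computed_splitplot_oracle(self, splitplot_toy):
        table = mixed_anova(splitplot_toy)
        hand = _hand_splitplot(splitplot_toy)
        get = lambda eff: float(table.loc[table["effect"] == eff, "ss"].iloc[0])
        assert get("delay_group") == pytest.approx(hand["group"], abs=1e-10)
        assert get("subjects(delay_group)") == pytest.approx(hand["err_b"], abs=1e-10)
        assert get("lop_condition") == pytest.approx(hand["level"], abs=1e-10)
        assert get("lop_condition:delay_group") == pytest.approx(hand["inter"], abs=1e-10)
        assert get("within_error") == pytest.approx(hand["err_w"], abs=1e-10)

    def test_balanced_strata_sum_to_total(self, splitplot_toy):
        table = mixed_anova(splitplot_toy)
        hand = _hand_splitplot(splitplot_toy)
        effects = ["delay_group", "subjects(delay_group)", "lop_condition",
                   "lop_condition:delay_group", "within_error"]
        total = sum(
            float(table.loc[table["effect"] == e, "ss"].iloc[0]) for e in effects
        )
        assert total == pytest.approx(hand["total"], abs=1e-10)

    def test_cross_check_against_pingouin_on_balanced_data(self, splitplot_toy):
        pg = pytest.importorskip("pingouin")
        ours = mixed_anova(splitplot_toy)
        theirs = pg.mixed_anova(
            data=splitplot_toy, dv="d_prime", within="lop_condition",
            between="delay_group", subject="participant_id",
        )
        pairs = {"delay_group": "delay_group", "lop_condition": "lop_condition",
                 "Interaction": "lop_condition:delay_group"}
        for pg_name, our_name in pairs.items():
            F_pg = float(theirs.loc[theirs["Source"] == pg_name, "F"].iloc[0])
            F_us = float(ours.loc[ours["effect"] == our_name, "F"].iloc[0])
            assert F_us == pytest.approx(F_pg, rel=1e-6)

    def test_null_level_construction_gives_zero_f(self):
        rows = []
        for g, group in enumerate(["g1", "g2"]):
            for s in range(4):
                base = 1.0 + 0.3 * s + g
                for level in ("deep", "shallow"):
                    rows.append({"participant_id": f"{group}{s}", "delay_group": group,
                                 "lop_condition": level, "d_prime": base})
        table = mixed_anova(pd.DataFrame(rows))
        f_level = float(table.loc[table["effect"] == "lop_condition", "F"].iloc[0])
        assert f_level == 0.0

    def test_partial_eta_squared_identity(self, splitplot_toy):
        table = mixed_anova(splitplot_toy)
        err_b = float(table.loc[table.effect == "subjects(delay_group)", "ss"].iloc[0])
        err_w = float(table.loc[table.effect == "within_error", "ss"].iloc[0])
        for eff, err in [("delay_group", err_b), ("lop_condition", err_w),
                         ("lop_condition:delay_group", err_w)]:
            row = table.loc[table["effect"] == eff].iloc[0]
            assert row["partial_eta_sq"] == pytest.approx(
                row["ss"] / (row["ss"] + err), abs=1e-12
            )

    def test_listwise_drop_warns(self, splitplot_toy):
        broken = splitplot_toy.drop(index=0)
        with pytest.warns(UserWarning, match="listwise"):
            table = mixed_anova(broken)
        assert table.attrs["n_subjects"] == 11

    def test_type1_error_of_interaction_and_power_of_level(self):
        """Planted 0.5-d' level effect: level test has high power, the null
        interaction rejects at ~5%."""
        rng = np.random.default_rng(99)
        n_rep, n_per = 400, 30
        groups = np.repeat(["g1", "g2", "g3"], n_per)
        rej_level = rej_inter = 0
        for _ in range(n_rep):
            subj_eff = rng.normal(0, 0.5, 3 * n_per)
            deep = 2.0 + subj_eff + rng.normal(0, 0.4, 3 * n_per)
            shallow = 1.5 + subj_eff + rng.normal(0, 0.4, 3 * n_per)
            df = pd.DataFrame(
                {
                    "participant_id": np.repeat(np.arange(3 * n_per), 2),
                    "delay_group": np.repeat(groups, 2),
                    "lop_condition": np.tile(["deep", "shallow"], 3 * n_per),
                    "d_prime": np.column_stack([deep, shallow]).ravel(),
                }
            )
            table = mixed_anova(df)
            p_level = float(table.loc[table.effect == "lop_condition", "p"].iloc[0])
            p_inter = float(
                table.loc[table.effect == "lop_condition:delay_group", "p"].iloc[0]
            )
            rej_level += p_level < 0.05
            rej_inter += p_inter < 0.05
        assert rej_level / n_rep > 0.95
        assert 0.02 <= rej_inter / n_rep <= 0.085


class TestFactorialAnova:
    @staticmethod
    def _toy(unbalanced=False, seed=1):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("deep", "shallow"):
            for b in ("g1", "g2", "g3"):
                n = rng.integers(4, 9) if unbalanced else 5
                for _ in range(n):
                    rows.append({"lop_condition": a, "delay_group": b,
                                 "d_prime": float(rng.normal(1 + (a == "deep"), 0.5))})
        return pd.DataFrame(rows)

    def test_equal_cell_means_give_zero_f(self):
        rows = [
            {"lop_condition": a, "delay_group": b, "d_prime": d}
            for a in ("deep", "shallow") for b in ("g1", "g2")
            for d in (1.0, 2.0)  # same within-cell values everywhere
        ]
        table = factorial_anova(pd.DataFrame(rows))
        for eff in ("lop_condition", "delay_group", "lop_condition:delay_group"):
            assert float(table.loc[table["effect"] == eff, "F"].iloc[0]) == pytest.approx(
                0.0, abs=1e-20
            )

    def test_type2_equals_projection_oracle_when_unbalanced(self):
        df = self._toy(unbalanced=True)
        table = factorial_anova(df)

        # independent oracle: R(effect | others respecting marginality) by
        # explicit least-squares projections
        def dummies(s):
            codes = pd.Categorical(s).codes
            out = np.zeros((len(s), codes.max() + 1))
            out[np.arange(len(s)), codes] = 1
            return out[:, 1:]

        y = df["d_prime"].to_numpy()
        one = np.ones((len(df), 1))
        A, B = dummies(df["lop_condition"]), dummies(df["delay_group"])
        AB = np.column_stack([A[:, i:i+1] * B[:, j:j+1]
                              for i in range(A.shape[1]) for j in range(B.shape[1])])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        ss_a = rss(np.column_stack([one, B])) - rss(np.column_stack([one, A, B]))
        ss_b = rss(np.column_stack([one, A])) - rss(np.column_stack([one, A, B]))
        ss_ab = rss(np.column_stack([one, A, B])) - rss(np.column_stack([one, A, B, AB]))
        get = lambda eff: float(table.loc[table["effect"] == eff, "ss"].iloc[0])
        assert get("lop_condition") == pytest.approx(ss_a, abs=1e-8)
        assert get("delay_group") == pytest.approx(ss_b, abs=1e-8)
        assert get("lop_condition:delay_group") == pytest.approx(ss_ab, abs=1e-8)

    def test_balanced_type2_equals_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self._toy(unbalanced=False)
        table = factorial_anova(df)
        m = smf.ols("d_prime ~ C(lop_condition) * C(delay_group)", data=df).fit()
        t1 = sm.stats.anova_lm(m, typ=1)
        assert float(table.loc[table.effect == "lop_condition", "ss"].iloc[0]) == (
            pytest.approx(float(t1.loc["C(lop_condition)", "sum_sq"]), abs=1e-8)
        )


class TestPosthocs:
    def test_identical_groups_bonferroni_p_is_one(self):
        df = pd.DataFrame(
            {"g": ["a"] * 4 + ["b"] * 4, "y": [1.0, 2.0, 3.0, 4.0] * 2}
        )
        out = bonferroni_pairwise(df, "y", "g")
        assert out["p_adjusted"].iloc[0] == pytest.approx(1.0)

    def test_single_different_pair_flagged(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "y": [1.0, 1.01, 0.99, 1.0] * 2 + [5.0, 5.01, 4.99, 5.0],
            }
        )
        out = tukey_hsd(df, "y", "g")
        sig = out[out["p_adjusted"] < 0.01]["pair"].tolist()
        assert sig == ["a vs c", "b vs c"]
        assert out.loc[out["pair"] == "a vs b", "p_adjusted"].iloc[0] > 0.5

    def test_tukey_q_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 10), "y": rng.normal(0, 1, 30)}
        )
        out = tukey_hsd(df, "y", "g")
        means = df.groupby("g")["y"].mean()
        mse = df.groupby("g")["y"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum() / 27
        q = abs(means["a"] - means["b"]) / np.sqrt(mse / 10)
        row = out[out["pair"] == "a vs b"].iloc[0]
        assert row["q"] == pytest.approx(q, abs=1e-8)
        assert row["p_adjusted"] == pytest.approx(
            stats.studentized_range.sf(q, 3, 27), abs=1e-8
        )

    def test_tukey_cross_check_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 12),
             "y": rng.normal([0, 0.5, 1.0], 1, size=(12, 3)).T.ravel()}
        )
        ours = tukey_hsd(df, "y", "g")
        theirs = pairwise_tukeyhsd(df["y"], df["g"])
        for (_, row), p_sm in zip(ours.iterrows(), theirs.pvalues):
            assert row["p_adjusted"] == pytest.approx(p_sm, abs=1e-6)

    def test_bonferroni_adjustment_identity(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 8), "y": rng.normal(0, 1, 24)}
        )
        out = bonferroni_pairwise(df, "y", "g")
        assert np.allclose(out["p_adjusted"], np.minimum(1.0, 3 * out["p_raw"]))
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()


class TestBayesFactors:
    def test_identical_models_bf_one(self):
        res = bayes_factor_bic(123.4, 123.4)
        assert res.bf10 == pytest.approx(1.0)
        assert res.category == "negligible"

    def test_category_boundary_arithmetic(self):
        res = bayes_factor_bic(2 * np.log(151.0), 0.0)  # BF10 = 151
        assert res.bf10 == pytest.approx(151.0)
        assert res.category == "very strong"
        assert res.bf01 == pytest.approx(1 / 151.0)

    @pytest.mark.parametrize("bf,cat", [
        (1.5, "negligible"), (10.0, "positive"), (100.0, "strong"), (151.0, "very strong"),
    ])
    def test_kass_raftery_bins(self, bf, cat):
        assert kass_raftery_category(bf) == cat

    def test_large_planted_effect_lands_very_strong(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 30
            subj = rng.normal(0, 0.3, 3 * n)
            df = pd.DataFrame(
                {
                    "participant_id": np.repeat(np.arange(3 * n), 2),
                    "delay_group": np.repeat(["g1", "g2", "g3"], 2 * n),
                    "lop_condition": np.tile(["deep", "shallow"], 3 * n),
                    "d_prime": np.column_stack(
                        [2.6 + subj + rng.normal(0, 0.35, 3 * n),
                         2.0 + subj + rng.normal(0, 0.35, 3 * n)]
                    ).ravel(),
                }
            )
            bf = anova_bayes_factors(df)
            row = bf[bf["effect"] == "lop_condition"].iloc[0]
            hits += (row["favoured"] == "alternative") and (row["category"] == "very strong")
        assert hits / n_rep >= 0.95

    def test_mixed_design_between_effect_not_degenerate(self):
        rng = np.random.default_rng(3)
        n = 20
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(3 * n), 2),
                "delay_group": np.repeat(["g1", "g2", "g3"], 2 * n),
                "lop_condition": np.tile(["deep", "shallow"], 3 * n),
                "d_prime": np.repeat([2.5, 1.5, 0.5], 2 * n)
                + rng.normal(0, 0.3, 6 * n),
            }
        )
        bf = anova_bayes_factors(df)
        row = bf[bf["effect"] == "delay_group"].iloc[0]
        assert row["bf10"] > 150


class TestLogRT:
    def test_mean_log_of_exponential_rts(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p1"] * 2,
                "lop_condition": ["deep"] * 2,
                "delay_group": ["2h"] * 2,
                "item_role": ["target"] * 2,
                "rt_ms": [np.e, np.e**3],
            }
        )
        out = log_transform_rt(trials)
        assert out["mean_log_rt"].iloc[0] == pytest.approx(2.0)

    def test_nonpositive_rts_dropped_with_count(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p1"] * 3,
                "lop_condition": ["deep"] * 3,
                "delay_group": ["2h"] * 3,
                "item_role": ["target"] * 3,
                "rt_ms": [np.e, 0.0, -5.0],
            }
        )
        with pytest.warns(UserWarning, match="2 non-positive"):
            out = log_transform_rt(trials)
        assert out.attrs["n_dropped"] == 2
        assert out["mean_log_rt"].iloc[0] == pytest.approx(1.0)

    def test_simulated_level_difference_recovered(self, exp1_trials):
        out = log_transform_rt(exp1_trials)
        wide = out.pivot_table(index="participant_id", columns="lop_condition",
                               values="mean_log_rt")
        # generative log-means differ by 7.91 - 7.58 = 0.33
        assert (wide["deep"] - wide["shallow"]).mean() == pytest.approx(0.33, abs=0.05)
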