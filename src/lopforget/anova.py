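"""Split-plot and factorial ANOVA with Type II SS, post hocs and Bayes factors.

The split-plot (mixed) design has one between-participants factor (delay
group) and one within-participants factor (encoding level). Sums of squares
are computed by model comparison on explicit dummy codings respecting
marginality (Type II): the between stratum tests the group effect against
subjects-within-groups, and the within stratum tests the level effect and the
level x group interaction against the level x subject residual. Because every
participant contributes each level exactly once, the group and level factors
are orthogonal under the weighted coding, so Type II and Type I sums of
squares coincide for balanced group sizes and differ only through the
marginality-respecting projections when group ns are unequal.

Fully between-participants factorial tables delegate to statsmodels
``anova_lm(typ=2)``. Effect size is partial eta^2 =
SS_effect / (SS_effect + SS_error-of-that-stratum). Bayes factors use the
BIC (unit-information-prior) approximation BF01 = exp((BIC_alt - BIC_null)/2)
and are binned into the conventional evidence categories with boundaries at
1, 3, 20 and 150.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mixed_anova",
    "factorial_anova",
    "bonferroni_pairwise",
    "tukey_hsd",
    "bayes_factor_bic",
    "anova_bayes_factors",
    "kass_raftery_category",
    "log_transform_rt",
    "BayesResult",
]

KASS_RAFTERY_BINS = (1.0, 3.0, 20.0, 150.0)


# ---------------------------------------------------------------- mixed ANOVA


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((codes.size, k))
    out[np.arange(codes.size), codes] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mixed_anova(
    scores: pd.DataFrame,
    dv: str = "d_prime",
    within: str = "lop_condition",
    between: str = "delay_group",
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Two-way split-plot ANOVA (Type II SS, separate error strata).

    ``scores`` holds one row per subject x within-level. Subjects with
    missing cells are dropped listwise with a warning. Returns a table with
    rows (between effect, between error, within effect, interaction, within
    error) carrying SS, df, MS, F, p and partial eta^2.
    """
    df = scores[[subject, within, between, dv]].dropna()
    levels = sorted(df[within].unique())
    L = len(levels)
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"{len(wide) - len(complete)} subject(s) with missing cells "
            "dropped listwise",
            stacklevel=2,
        )
    groups = complete.index.get_level_values(between)
    group_names = sorted(set(groups))
    J = len(group_names)
    if J < 2 or L < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")

    # long arrays, one row per subject x level
    S = len(complete)
    y = complete.to_numpy(float)[:, [levels.index(l) for l in levels]].ravel()
    subj_code = np.repeat(np.arange(S), L)
    lev_code = np.tile(np.arange(L), S)
    grp_code = np.repeat(
        np.array([group_names.index(g) for g in groups]), L
    )

    Xs = _dummies(subj_code, S)  # spans intercept and group
    Xl = _dummies(lev_code, L)[:, 1:]  # treatment-coded level
    Xi = np.column_stack(
        [
            _dummies(grp_code, J)[:, j] * Xl[:, l]
            for j in range(1, J)
            for l in range(L - 1)
        ]
    )

    # within stratum: R(level | subjects), R(interaction | subjects, level)
    rss_s = _rss(Xs, y)
    rss_sl = _rss(np.column_stack([Xs, Xl]), y)
    rss_sli = _rss(np.column_stack([Xs, Xl, Xi]), y)
    # clamp numerically-zero SS (projection round-off on degenerate data)
    tol = 1e-12 * max(float(y @ y), 1.0)
    ss_level = max(rss_s - rss_sl, 0.0)
    ss_inter = max(rss_sl - rss_sli, 0.0)
    ss_err_w = rss_sli
    ss_level = 0.0 if ss_level < tol else ss_level
    ss_inter = 0.0 if ss_inter < tol else ss_inter
    ss_err_w = 0.0 if ss_err_w < tol else ss_err_w
    df_level = L - 1
    df_inter = (J - 1) * (L - 1)
    df_err_w = (S - J) * (L - 1)

    # between stratum: subject totals
    subj_means = complete.to_numpy(float).mean(axis=1)
    grp_of_subj = np.array([group_names.index(g) for g in groups])
    grand = subj_means.mean()
    n_j = np.bincount(grp_of_subj, minlength=J).astype(float)
    gmeans = np.bincount(grp_of_subj, weights=subj_means, minlength=J) / n_j
    ss_group = L * float(np.sum(n_j * (gmeans - grand) ** 2))
    ss_err_b = L * float(np.sum((subj_means - gmeans[grp_of_subj]) ** 2))
    df_group = J - 1
    df_err_b = S - J

    balanced = len(set(n_j)) == 1

    def row(effect, ss, dfe, ss_err, df_err):
        ms = ss / dfe
        mse = ss_err / df_err
        if ms == 0.0:
            F = 0.0  # identically-null effect, even if the error MS is 0 too
        elif mse > 0:
            F = ms / mse
        else:
            F = np.nan
        p = float(stats.f.sf(F, dfe, df_err)) if np.isfinite(F) else np.nan
        return {
            "effect": effect, "ss": ss, "df": dfe, "ms": ms, "F": F, "p": p,
            "partial_eta_sq": ss / (ss + ss_err) if ss + ss_err > 0 else np.nan,
        }

    table = pd.DataFrame(
        [
            row(between, ss_group, df_group, ss_err_b, df_err_b),
            {"effect": f"subjects({between})", "ss": ss_err_b, "df": df_err_b,
             "ms": ss_err_b / df_err_b, "F": np.nan, "p": np.nan,
             "partial_eta_sq": np.nan},
            row(within, ss_level, df_level, ss_err_w, df_err_w),
            row(f"{within}:{between}", ss_inter, df_inter, ss_err_w, df_err_w),
            {"effect": "within_error", "ss": ss_err_w, "df": df_err_w,
             "ms": ss_err_w / df_err_w, "F": np.nan, "p": np.nan,
             "partial_eta_sq": np.nan},
        ]
    )
    table.attrs["ss_type"] = "II" if not balanced else "II (= I, balanced)"
    table.attrs["n_subjects"] = S
    return table


# ------------------------------------------------------------ factorial ANOVA


def factorial_anova(
    scores: pd.DataFrame,
    dv: str = "d_prime",
    factor_a: str = "lop_condition",
    factor_b: str = "delay_group",
) -> pd.DataFrame:
    """Fully between-participants two-way ANOVA with Type II SS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = scores[[factor_a, factor_b, dv]].dropna().copy()
    df.columns = ["A", "B", "y"]
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_err = float(aov.loc["Residual", "sum_sq"])
    rows = []
    label = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    for name in ["C(A)", "C(B)", "C(A):C(B)"]:
        ss = float(aov.loc[name, "sum_sq"])
        dfe = float(aov.loc[name, "df"])
        rows.append(
            {
                "effect": label[name], "ss": ss, "df": dfe, "ms": ss / dfe,
                "F": float(aov.loc[name, "F"]), "p": float(aov.loc[name, "PR(>F)"]),
                "partial_eta_sq": ss / (ss + ss_err),
            }
        )
    dfr = float(aov.loc["Residual", "df"])
    rows.append(
        {"effect": "error", "ss": ss_err, "df": dfr, "ms": ss_err / dfr,
         "F": np.nan, "p": np.nan, "partial_eta_sq": np.nan}
    )
    out = pd.DataFrame(rows)
    counts = df.groupby(["A", "B"]).size()
    out.attrs["ss_type"] = "II" if counts.nunique() > 1 else "II (= I, balanced)"
    return out


# -------------------------------------------------------------------- posthoc


def _pairwise_frame(values: pd.Series, factor: pd.Series):
    levels = sorted(factor.unique())
    if len(levels) < 2:
        raise ValueError("post hoc needs >= 2 groups")
    data = {g: values[factor == g].to_numpy(float) for g in levels}
    return levels, data


def bonferroni_pairwise(
    scores: pd.DataFrame,
    dv: str,
    factor: str,
    error_ms: float | None = None,
    error_df: float | None = None,
) -> pd.DataFrame:
    """Pairwise t-tests with Bonferroni-adjusted p and Cohen's d.

    Uses the supplied stratum error MS/df when given (e.g. the
    subjects-within-groups MS of a split-plot); otherwise pools the
    within-group variance across all groups. Cohen's d divides the mean
    difference by sqrt(error MS).
    """
    levels, data = _pairwise_frame(scores[dv], scores[factor])
    if error_ms is None:
        ss = sum(((v - v.mean()) ** 2).sum() for v in data.values())
        error_df = sum(len(v) - 1 for v in data.values())
        error_ms = ss / error_df
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        x1, x2 = data[g1], data[g2]
        diff = x1.mean() - x2.mean()
        se = np.sqrt(error_ms * (1 / len(x1) + 1 / len(x2)))
        tval = diff / se if se > 0 else np.nan
        p_raw = 2 * stats.t.sf(abs(tval), error_df) if np.isfinite(tval) else np.nan
        rows.append(
            {
                "pair": f"{g1} vs {g2}", "t": tval, "df": error_df,
                "p_raw": p_raw, "p_adjusted": min(1.0, m * p_raw) if np.isfinite(tval) else np.nan,
                "cohens_d": diff / np.sqrt(error_ms),
                "adjustment": "bonferroni",
            }
        )
    return pd.DataFrame(rows)


def tukey_hsd(
    scores: pd.DataFrame,
    dv: str,
    factor: str,
    error_ms: float | None = None,
    error_df: float | None = None,
) -> pd.DataFrame:
    """Tukey-Kramer HSD via the studentized range distribution."""
    levels, data = _pairwise_frame(scores[dv], scores[factor])
    k = len(levels)
    if error_ms is None:
        ss = sum(((v - v.mean()) ** 2).sum() for v in data.values())
        error_df = sum(len(v) - 1 for v in data.values())
        error_ms = ss / error_df
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        x1, x2 = data[g1], data[g2]
        diff = x1.mean() - x2.mean()
        se_q = np.sqrt(error_ms / 2.0 * (1 / len(x1) + 1 / len(x2)))
        q = abs(diff) / se_q if se_q > 0 else np.nan
        p = float(stats.studentized_range.sf(q, k, error_df)) if np.isfinite(q) else np.nan
        rows.append(
            {
                "pair": f"{g1} vs {g2}", "q": q, "df": error_df,
                "p_adjusted": min(1.0, p), "cohens_d": diff / np.sqrt(error_ms),
                "adjustment": "tukey_hsd",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- Bayes factor


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    bf01: float
    category: str
    favoured: str  # "alternative" | "null" | "neither"
    method: str = "BIC-approximate (unit-information prior)"


def kass_raftery_category(bf: float) -> str:
    """Evidence category for a Bayes factor >= 1 (bins at 1, 3, 20, 150)."""
    if bf < KASS_RAFTERY_BINS[0]:
        raise ValueError("categorise the BF of the favoured hypothesis (>= 1)")
    if bf <= KASS_RAFTERY_BINS[1]:
        return "negligible"
    if bf <= KASS_RAFTERY_BINS[2]:
        return "positive"
    if bf <= KASS_RAFTERY_BINS[3]:
        return "strong"
    return "very strong"


def bayes_factor_bic(bic_null: float, bic_alt: float) -> BayesResult:
    """Bayes factor for the alternative from two nested models' BICs.

    BF10 ~= exp((BIC_null - BIC_alt) / 2). The caller is responsible for the
    models being nested fits of the same data.
    """
    bf10 = float(np.exp((bic_null - bic_alt) / 2.0))
    bf01 = 1.0 / bf10
    if bf10 >= 1.0:
        return BayesResult(bf10, bf01, kass_raftery_category(bf10), "alternative" if bf10 > 1 else "neither")
    return BayesResult(bf10, bf01, kass_raftery_category(bf01), "null")


def _ols_bic(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    rss = _rss(X, y)
    k = np.linalg.matrix_rank(X) + 1  # + sigma
    return n * np.log(2 * np.pi * rss / n) + n + k * np.log(n)


def _fcodes(s: pd.Series) -> np.ndarray:
    codes = pd.Categorical(s).codes
    return _dummies(codes, codes.max() + 1)[:, 1:]


def anova_bayes_factors(
    scores: pd.DataFrame,
    dv: str = "d_prime",
    within: str | None = "lop_condition",
    between: str = "delay_group",
    subject: str = "participant_id",
    factor_a: str = "lop_condition",
) -> pd.DataFrame:
    """BIC-approximate Bayes factors for each ANOVA effect.

    Each effect is evaluated by comparing nested linear models with and
    without it, respecting marginality and the design's error strata. In the
    mixed design (``within`` given) the level and interaction effects are
    compared with the subject dummies in both models, while the
    between-participants effect is compared on the subject means (the
    between stratum, where subject dummies would otherwise absorb it).
    ``within=None`` treats both ``factor_a`` and ``between`` as
    between-participants and uses plain OLS comparisons.
    """
    df = scores.dropna(subset=[dv]).copy()
    y = df[dv].to_numpy(float)
    rows = []

    if within is not None:
        ones = np.ones((len(df), 1))
        Xsub = np.column_stack([ones, _fcodes(df[subject])])
        Xlev = _fcodes(df[within])
        A, B = _fcodes(df[within]), _fcodes(df[between])
        inter = np.column_stack(
            [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
        )
        bic_s = _ols_bic(Xsub, y)
        bic_sl = _ols_bic(np.column_stack([Xsub, Xlev]), y)
        bic_sli = _ols_bic(np.column_stack([Xsub, Xlev, inter]), y)
        comparisons = [(within, bic_s, bic_sl),
                       (f"{within}:{between}", bic_sl, bic_sli)]
        means = df.groupby(subject).agg(y=(dv, "mean"), g=(between, "first"))
        ym = means["y"].to_numpy(float)
        ones_m = np.ones((len(means), 1))
        comparisons.insert(
            1,
            (
                between,
                _ols_bic(ones_m, ym),
                _ols_bic(np.column_stack([ones_m, _fcodes(means["g"])]), ym),
            ),
        )
    else:
        ones = np.ones((len(df), 1))
        A, B = _fcodes(df[factor_a]), _fcodes(df[between])
        inter = np.column_stack(
            [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
        )
        bic_ab = _ols_bic(np.column_stack([ones, A, B]), y)
        comparisons = [
            (factor_a, _ols_bic(np.column_stack([ones, B]), y), bic_ab),
            (between, _ols_bic(np.column_stack([ones, A]), y), bic_ab),
            (
                f"{factor_a}:{between}",
                bic_ab,
                _ols_bic(np.column_stack([ones, A, B, inter]), y),
            ),
        ]

    for effect, bic_null, bic_alt in comparisons:
        res = bayes_factor_bic(bic_null, bic_alt)
        rows.append(
            {
                "effect": effect, "bf10": res.bf10, "bf01": res.bf01,
                "favoured": res.favoured, "category": res.category,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------- RT


def log_transform_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean natural-log RT by encoding level (target rows).

    Non-positive RTs are dropped with their count recorded in
    ``result.attrs['n_dropped']``.
    """
    tgt = trials[trials["item_role"] == "target"].copy()
    bad = tgt["rt_ms"] <= 0
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-positive RT row(s)", stacklevel=2)
        tgt = tgt[~bad]
    tgt["log_rt"] = np.log(tgt["rt_ms"].astype(float))
    out = (
        tgt.groupby(["participant_id", "lop_condition", "delay_group"], sort=True)[
            "log_rt"
        ]
        .mean()
        .reset_index()
        .rename(columns={"log_rt": "mean_log_rt"})
    )
    out.attrs["n_dropped"] = n_dropped
    return out
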