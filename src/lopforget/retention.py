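"""Two-parameter retention (forgetting) functions and nested slope tests.

Recognition accuracy y (d' units) as a function of retention interval t
(hours) is modelled with four classical two-parameter laws:

    linear        y = a - b*t
    power         y = a * (t + 1)^(-b)
    exponential   y = a * exp(-b*t)
    logarithmic   y = a - b*ln(t + 1)

``a`` is the initial degree of learning (all four predict y = a at t = 0) and
``b`` the forgetting slope. Fits minimise the weighted residual sum of squares
sum_i w_i (y_i - f(t_i))^2; fitting trial-level points with unit weights and
fitting cell means weighted by cell n give identical point estimates, because
the within-cell scatter is orthogonal to any function of t.

Slope equality between two encoding conditions is tested by refitting one
condition with its slope fixed at the other condition's estimate (intercept
re-estimated in closed form) and comparing nested fits with the Gaussian
likelihood-ratio statistic chi^2 = N * ln(RSS_constrained / RSS_unconstrained)
on 1 df, where the RSS totals include the within-cell sum of squares when the
fit was done on cell means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import RETENTION_FORMS

__all__ = [
    "evaluate",
    "fit",
    "fit_constrained",
    "goodness_of_fit",
    "compare_slopes",
    "fit_all_functions",
    "within_cell_ss",
    "RetentionFit",
    "GoodnessOfFit",
    "SlopeComparison",
]

# Forms split by how b enters: multiplicative basis y = a*u(t; b), or a
# shifted linear form y = a - b*g(t). Both admit a closed-form intercept
# given b, so the 2-parameter problem profiles to a 1-D search over b
# (and the shifted forms are exactly linear in (a, b)).
_MULTIPLICATIVE: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "power": lambda t, b: np.power(t + 1.0, -b),
    "exponential": lambda t, b: np.exp(-b * t),
}
_SHIFT_BASIS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda t: np.asarray(t, float),
    "logarithmic": lambda t: np.log(np.asarray(t, float) + 1.0),
}


def evaluate(form: str, a: float, b: float, t) -> np.ndarray | float:
    """Evaluate retention function `form` at delay(s) t (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("delays t must be >= 0")
    if form in _MULTIPLICATIVE:
        out = a * _MULTIPLICATIVE[form](t_arr, b)
    elif form in _SHIFT_BASIS:
        out = a - b * _SHIFT_BASIS[form](t_arr)
    else:
        raise ValueError(f"unknown retention form {form!r}")
    return out if np.ndim(t) else float(out)


@dataclass
class RetentionFit:
    """Weighted least-squares fit of one retention function."""

    form: str
    a: float
    b: float
    se_a: float
    se_b: float
    rss: float  # weighted between-point RSS at the data resolution fitted
    n_points: int
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    constrained: bool = False
    b_source: str = "free"
    within_ss: float = 0.0  # within-cell SS when fitted on cell means
    n_total: int | None = None  # trial-level N behind the cells

    @property
    def total_rss(self) -> float:
        """RSS at trial-level resolution (between + within components)."""
        return self.rss + self.within_ss

    @property
    def n_effective(self) -> int:
        return self.n_total if self.n_total is not None else self.n_points

    def predict(self, t) -> np.ndarray | float:
        return evaluate(self.form, self.a, self.b, t)


@dataclass(frozen=True)
class GoodnessOfFit:
    aic: float
    bic: float
    r_squared: float
    n: int
    k: int = 3
    convention: str = "gaussian -2lnL with profiled sigma; k = 3 (a, b, sigma)"


@dataclass(frozen=True)
class SlopeComparison:
    chi_square: float
    df: int
    p: float
    direction: str
    rss_unconstrained: float
    rss_constrained: float
    n: int


def _prepare(t, y, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if not (t.shape == y.shape == w.shape):
        raise ValueError("t, y and weights must have matching shapes")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(t < 0):
        raise ValueError("delays t must be >= 0")
    return t, y, w


def _profiled_a(form: str, b: float, t, y, w) -> float:
    """Closed-form weighted LS intercept for fixed slope b."""
    if form in _MULTIPLICATIVE:
        u = _MULTIPLICATIVE[form](t, b)
        denom = float(np.sum(w * u * u))
        if denom == 0.0:
            raise ValueError("degenerate basis: all u_i = 0 for the fixed b")
        return float(np.sum(w * y * u) / denom)
    g = _SHIFT_BASIS[form](t)
    return float(np.sum(w * (y + b * g)) / np.sum(w))


def _rss_at(form: str, a: float, b: float, t, y, w) -> float:
    r = y - evaluate(form, a, b, t)
    return float(np.sum(w * r * r))


def _profile_rss(form: str, b: float, t, y, w) -> float:
    return _rss_at(form, _profiled_a(form, b, t, y, w), b, t, y, w)


# Deterministic multi-start grid for the slope search: log-spaced positive
# starts 0.01..4 plus 0 and mirrored negative starts, so sign is unconstrained
# and a wrong-signed slope remains detectable.
_B_STARTS = np.concatenate(
    [-np.geomspace(0.01, 4.0, 12)[::-1], [0.0], np.geomspace(0.01, 4.0, 25)]
)


def _hessian_se(form, a, b, t, y, w, total_rss, n_eff) -> tuple[float, float]:
    """SEs from the Gauss-Newton covariance sigma^2 (J' W J)^-1."""
    if form in _MULTIPLICATIVE:
        u = _MULTIPLICATIVE[form](t, b)
        if form == "power":
            du = -np.log(t + 1.0) * u  # d u / d b
        else:
            du = -t * u
        J = np.column_stack([u, a * du])
    else:
        g = _SHIFT_BASIS[form](t)
        J = np.column_stack([np.ones_like(t), -g])
    JtWJ = J.T @ (w[:, None] * J)
    dof = max(n_eff - 2, 1)
    sigma2 = total_rss / dof
    try:
        cov = sigma2 * np.linalg.inv(JtWJ)
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def fit(
    form: str,
    t: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    within_ss: float = 0.0,
    n_total: int | None = None,
) -> RetentionFit:
    """Unconstrained weighted least-squares fit of a two-parameter form.

    Parameters
    ----------
    t, y
        Delays (hours) and d' values: either trial-level points (weights
        omitted) or cell means with ``weights`` = cell ns.
    within_ss, n_total
        When fitting cell means, the within-cell sum of squares and the
        trial-level N behind the cells; carried so likelihood-based
        statistics can be formed at trial-level resolution.
    """
    if form not in RETENTION_FORMS:
        raise ValueError(f"unknown retention form {form!r}")
    t, y, w = _prepare(t, y, weights)
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct delays for a 2-parameter fit")

    if form in _SHIFT_BASIS:
        # Exactly linear in (a, b): solve the weighted normal equations.
        g = _SHIFT_BASIS[form](t)
        X = np.column_stack([np.ones_like(t), -g])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
        a_hat, b_hat = float(coef[0]), float(coef[1])
    else:
        # Profile likelihood in b with deterministic multi-start refinement.
        objective = lambda b: _profile_rss(form, b, t, y, w)  # noqa: E731
        best: tuple[float, float] | None = None
        for b0 in _B_STARTS:
            if _is_bracket(form, b0, t, y, w):
                res = optimize.minimize_scalar(
                    objective, bracket=(b0 - 0.25, b0, b0 + 0.25),
                    method="brent", options={"xtol": 1e-12},
                )
            else:
                res = optimize.minimize_scalar(
                    objective, bounds=(b0 - 2.0, b0 + 2.0),
                    method="bounded", options={"xatol": 1e-12},
                )
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                best = (float(res.fun), float(res.x))
        if best is None:
            raise RuntimeError("retention fit failed to converge from any start")
        b_hat = best[1]
        a_hat = _profiled_a(form, b_hat, t, y, w)

    rss = _rss_at(form, a_hat, b_hat, t, y, w)
    n_eff = n_total if n_total is not None else len(t)
    se_a, se_b = _hessian_se(form, a_hat, b_hat, t, y, w, rss + within_ss, n_eff)
    return RetentionFit(
        form=form, a=a_hat, b=b_hat, se_a=se_a, se_b=se_b, rss=rss,
        n_points=len(t), t=t, y=y, weights=w,
        within_ss=float(within_ss), n_total=n_total,
    )


def _is_bracket(form, b0, t, y, w) -> bool:
    """True if (b0-0.25, b0, b0+0.25) is a valid Brent bracket."""
    try:
        f0 = _profile_rss(form, b0, t, y, w)
        return (
            _profile_rss(form, b0 - 0.25, t, y, w) > f0
            and _profile_rss(form, b0 + 0.25, t, y, w) > f0
        )
    except (ValueError, FloatingPointError, OverflowError):
        return False


def fit_constrained(
    form: str,
    t: Sequence[float],
    y: Sequence[float],
    b_fixed: float,
    weights: Sequence[float] | None = None,
    within_ss: float = 0.0,
    n_total: int | None = None,
    b_source: str = "fixed-from-other-condition",
) -> RetentionFit:
    """Fit with the slope fixed; only the intercept is estimated (closed form)."""
    if form not in RETENTION_FORMS:
        raise ValueError(f"unknown retention form {form!r}")
    t, y, w = _prepare(t, y, weights)
    a_hat = _profiled_a(form, b_fixed, t, y, w)
    rss = _rss_at(form, a_hat, b_fixed, t, y, w)
    n_eff = n_total if n_total is not None else len(t)
    se_a, _ = _hessian_se(form, a_hat, b_fixed, t, y, w, rss + within_ss, n_eff)
    return RetentionFit(
        form=form, a=a_hat, b=float(b_fixed), se_a=se_a, se_b=float("nan"),
        rss=rss, n_points=len(t), t=t, y=y, weights=w,
        constrained=True, b_source=b_source,
        within_ss=float(within_ss), n_total=n_total,
    )


def within_cell_ss(se: Sequence[float], n: Sequence[int]) -> float:
    """Within-cell sum of squares reconstructed from cell SEs and ns.

    SE = SD/sqrt(n) implies SD^2 = n*SE^2 and SS_cell = (n-1)*SD^2, so the
    within component a trial-level fit would add to the between-cell RSS is
    sum_cells (n-1)*n*SE^2.
    """
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    return float(np.sum((n - 1.0) * n * se**2))


def goodness_of_fit(fit_result: RetentionFit) -> GoodnessOfFit:
    """AIC/BIC/R^2 under the Gaussian-likelihood convention.

    AIC = N ln(2 pi RSS/N) + N + 2k and BIC = N ln(2 pi RSS/N) + N + k ln N
    with k = 3 (a, b, sigma), computed on the trial-level total RSS. When the
    fit came from cell means, the within-cell SS must have been supplied
    whenever the trial-level N exceeds the number of cells; otherwise only
    R^2 would be meaningful and an error is raised for AIC/BIC.
    """
    N = fit_result.n_effective
    if N > fit_result.n_points and fit_result.within_ss == 0.0:
        raise ValueError(
            "AIC/BIC need the within-cell SS when n_total exceeds the number "
            "of cells; supply within_ss (e.g. via within_cell_ss)"
        )
    rss = fit_result.total_rss
    w, y = fit_result.weights, fit_result.y
    ybar = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - ybar) ** 2)) + fit_result.within_ss
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if rss <= 0:
        return GoodnessOfFit(aic=-math.inf, bic=-math.inf, r_squared=1.0, n=N)
    k = 3
    core = N * math.log(2.0 * math.pi * rss / N) + N
    return GoodnessOfFit(aic=core + 2 * k, bic=core + k * math.log(N), r_squared=r2, n=N)


def compare_slopes(
    unconstrained: RetentionFit, constrained: RetentionFit
) -> SlopeComparison:
    """Likelihood-ratio test of slope equality from nested LS fits.

    chi^2 = N * ln(RSS_c / RSS_u) on 1 df (Gaussian likelihood with profiled
    variance), computed on trial-level total RSS.
    """
    if unconstrained.form != constrained.form:
        raise ValueError("fits compare different retention forms")
    if not constrained.constrained or unconstrained.constrained:
        raise ValueError("expected (unconstrained, constrained) in that order")
    if (
        unconstrained.n_points != constrained.n_points
        or not np.allclose(unconstrained.t, constrained.t)
        or not np.allclose(unconstrained.weights, constrained.weights)
        or not np.allclose(unconstrained.y, constrained.y)
    ):
        raise ValueError("fits must be on identical data with identical weights")
    n = unconstrained.n_effective
    if n != constrained.n_effective:
        raise ValueError("fits carry different trial-level N")
    rss_u, rss_c = unconstrained.total_rss, constrained.total_rss
    if rss_c < rss_u - 1e-9 * max(rss_u, 1.0):
        raise ValueError(
            f"constrained RSS {rss_c} < unconstrained RSS {rss_u}: optimiser failure"
        )
    chi2 = max(0.0, n * math.log(rss_c / rss_u))
    return SlopeComparison(
        chi_square=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0,
        direction=constrained.b_source,
        rss_unconstrained=rss_u,
        rss_constrained=rss_c,
        n=n,
    )


def fit_all_functions(
    cells: pd.DataFrame,
    forms: Sequence[str] = RETENTION_FORMS,
) -> pd.DataFrame:
    """Fit every retention form to every condition's cell means.

    ``cells`` needs columns condition, t_hours, mean, se, n (the shape of the
    published per-cell summaries). Returns one row per condition x form with
    parameters, RSS, AIC, BIC, R^2 and the within-condition rank under each
    criterion; ranks by AIC, BIC and R^2 are asserted to agree (they are all
    monotone in RSS at fixed N and k) and a ``rank_agreement`` flag records it.
    """
    rows = []
    for condition, sub in cells.groupby("condition", sort=False):
        wss = within_cell_ss(sub["se"], sub["n"])
        n_total = int(sub["n"].sum())
        for form in forms:
            f = fit(form, sub["t_hours"], sub["mean"], weights=sub["n"],
                    within_ss=wss, n_total=n_total)
            gof = goodness_of_fit(f)
            rows.append(
                {
                    "condition": condition, "form": form,
                    "a": f.a, "b": f.b, "se_a": f.se_a, "se_b": f.se_b,
                    "rss": f.total_rss, "n": gof.n,
                    "aic": gof.aic, "bic": gof.bic, "r_squared": gof.r_squared,
                }
            )
    out = pd.DataFrame(rows)
    for crit, ascending in [("aic", True), ("bic", True), ("r_squared", False)]:
        out[f"rank_{crit}"] = (
            out.groupby("condition")[crit]
            .rank(method="first", ascending=ascending)
            .astype(int)
        )
    out["rank_agreement"] = (out["rank_aic"] == out["rank_bic"]) & (
        out["rank_aic"] == out["rank_r_squared"]
    )
    return out


def slope_equality_analysis(
    cells: pd.DataFrame,
    form: str = "power",
    donor: str = "deep",
    recipient: str = "shallow",
) -> dict:
    """Full slope-equality analysis on a per-cell summary table.

    Fits the ``form`` unconstrained to both conditions (cell means weighted by
    cell n, with within-cell SS reconstructed from the SEs), refits the
    ``recipient`` condition with its slope fixed at the ``donor`` condition's
    estimate, and runs the likelihood-ratio test. Returns a dict with keys
    ``unconstrained`` (per condition), ``constrained`` and ``comparison``.
    """
    fits: dict[str, RetentionFit] = {}
    for condition, sub in cells.groupby("condition", sort=False):
        fits[condition] = fit(
            form, sub["t_hours"], sub["mean"], weights=sub["n"],
            within_ss=within_cell_ss(sub["se"], sub["n"]),
            n_total=int(sub["n"].sum()),
        )
    if donor not in fits or recipient not in fits:
        raise ValueError(f"cells must contain conditions {donor!r} and {recipient!r}")
    sub = cells[cells["condition"] == recipient]
    constrained = fit_constrained(
        form, sub["t_hours"], sub["mean"], b_fixed=fits[donor].b,
        weights=sub["n"],
        within_ss=within_cell_ss(sub["se"], sub["n"]),
        n_total=int(sub["n"].sum()),
        b_source=f"fixed-from-{donor}",
    )
    comparison = compare_slopes(fits[recipient], constrained)
    return {"unconstrained": fits, "constrained": constrained, "comparison": comparison}
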