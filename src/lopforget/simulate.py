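"""Generative simulator of old/new recognition forgetting experiments.

The generative model is equal-variance signal detection with a latent
retention law. Participant i draws a shared intercept deviation
delta_i ~ N(0, sd_a^2) (so the two levels' intercepts are correlated in
within-participant designs), an absolute evidence criterion
c_i ~ N(criterion_mean, criterion_sd^2) and, with probability p_inattentive,
an "inattentive" flag. True discriminability at delay t under level L is
d'(t) = max(0, f(t; a_L + delta_i, b_L)). On each test trial the evidence is
N(d'(t), 1) for targets and N(0, 1) for distractors, and the response is
"old" iff evidence > c_i; inattentive participants flip a fair coin on every
trial. RTs are lognormal in log-ms, truncated at the encoding time limit.

Two outputs are provided: :func:`simulate_study` emits a tidy trial table
(one row per test trial) for pipeline testing, and
:func:`simulate_dprime_scores` aggregates the identical generative model to
per-participant corrected d' scores in fully vectorised form (hit and
false-alarm counts are binomial under the model), for Monte-Carlo
calibration and parameter-recovery studies at scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import GenerativeParams, StudyDesign, LEVELS
from .retention import evaluate

__all__ = ["simulate_study", "simulate_dprime_scores", "TRIAL_COLUMNS"]

#: Fixed column order of the trial table CSV.
TRIAL_COLUMNS = [
    "participant_id",
    "lop_condition",
    "delay_group",
    "phase",
    "delay_hours",
    "item_id",
    "item_role",
    "response",
    "rt_ms",
]


def _truncated_lognormal_ms(rng, mu, sigma, limit_ms, size):
    """Lognormal(mu, sigma) in log-ms, truncated above at limit_ms."""
    upper = norm.cdf((np.log(limit_ms) - mu) / sigma)
    u = rng.uniform(0.0, 1.0, size=size) * upper
    return np.exp(mu + sigma * norm.ppf(u))


def _latent_dprime(params: GenerativeParams, level: str, delta: float, t: float) -> float:
    form, a, b = params.level(level)
    a_i = max(0.0, a + delta)
    return max(0.0, float(evaluate(form, a_i, b, t)))


def simulate_study(
    design: StudyDesign,
    params: GenerativeParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one experiment; returns a tidy trial table.

    One row per recognition-test trial, columns in :data:`TRIAL_COLUMNS`.
    Within-design distractor rows carry ``lop_condition = "shared"``; in the
    between design every row carries the participant's condition. Item ids
    are disjoint between the immediate and delayed phase of a participant.
    Deterministic given the seed (``params.seed`` unless overridden here).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    conditions = [None] if design.lop_design == "within" else list(LEVELS)
    rows: list[tuple] = []
    pid_counter = 0

    for cond in conditions:
        for group in design.delay_groups:
            for _ in range(design.participants_per_group):
                pid_counter += 1
                pid = (
                    f"P{pid_counter:03d}"
                    if cond is None
                    else f"P{pid_counter:03d}_{cond}"
                )
                delta = rng.normal(0.0, params.sd_a)
                c_i = rng.normal(params.criterion_mean, params.criterion_sd)
                inattentive = rng.uniform() < params.p_inattentive
                levels = list(LEVELS) if cond is None else [cond]
                item_counter = 0
                for phase, t in (("immediate", 0.0), ("delayed", group.hours)):
                    phase_rows: list[tuple] = []
                    # targets, per level
                    for level in levels:
                        d = _latent_dprime(params, level, delta, t)
                        k = design.targets_per_level_per_phase
                        ev = rng.normal(d, 1.0, size=k)
                        if inattentive:
                            old = rng.uniform(size=k) < 0.5
                        else:
                            old = ev > c_i
                        mu = params.rt_mu_deep if level == "deep" else params.rt_mu_shallow
                        rt = _truncated_lognormal_ms(
                            rng, mu, params.rt_sigma, design.encoding_time_limit_ms, k
                        )
                        for j in range(k):
                            item_counter += 1
                            phase_rows.append(
                                (
                                    pid, level, group.label, phase, t,
                                    f"{pid}_it{item_counter:03d}", "target",
                                    "old" if old[j] else "new", round(float(rt[j]), 1),
                                )
                            )
                    # distractors, shared between levels in the within design
                    dis_level = "shared" if cond is None else cond
                    k = design.distractors_per_phase
                    ev = rng.normal(0.0, 1.0, size=k)
                    if inattentive:
                        old = rng.uniform(size=k) < 0.5
                    else:
                        old = ev > c_i
                    mu_d = (
                        0.5 * (params.rt_mu_deep + params.rt_mu_shallow)
                        if dis_level == "shared"
                        else (params.rt_mu_deep if cond == "deep" else params.rt_mu_shallow)
                    )
                    rt = _truncated_lognormal_ms(
                        rng, mu_d, params.rt_sigma, design.encoding_time_limit_ms, k
                    )
                    for j in range(k):
                        item_counter += 1
                        phase_rows.append(
                            (
                                pid, dis_level, group.label, phase, t,
                                f"{pid}_it{item_counter:03d}", "distractor",
                                "old" if old[j] else "new", round(float(rt[j]), 1),
                            )
                        )
                    rows.extend(phase_rows)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_dprime_scores(
    design: StudyDesign,
    params: GenerativeParams,
    n_replicates: int = 1,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised score-level draw from the same generative model.

    Skips per-trial rows: under the model, hit counts per cell are
    Binomial(n_targets, Phi(d' - c_i)) and false alarms are
    Binomial(n_distractors, Phi(-c_i)) (coin-flip binomials for inattentive
    participants), and in the within design the two levels share one
    distractor draw per phase, exactly as in :func:`simulate_study`. Rates
    receive the log-linear correction before the z-transform.

    Returns arrays keyed ``d_prime``, ``criterion``, ``hit_rate``,
    ``fa_rate`` of shape (n_replicates, n_participants, n_levels, n_phases)
    with phases ordered (immediate, delayed), plus ``group_hours`` and
    ``group_index`` of shape (n_participants,). In the between design
    participants are ordered deep-block then shallow-block and
    ``level_of_participant`` marks each participant's single condition
    (the level axis has length 1).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    within = design.lop_design == "within"
    n_groups = len(design.delay_groups)
    hours = np.array([g.hours for g in design.delay_groups])
    npg = design.participants_per_group
    n_cond_blocks = 1 if within else 2
    n_part = npg * n_groups * n_cond_blocks
    n_levels = 2 if within else 1
    R = n_replicates

    group_index = np.tile(np.repeat(np.arange(n_groups), npg), n_cond_blocks)
    group_hours = hours[group_index]
    if within:
        level_of_participant = None
        level_names = list(LEVELS)
    else:
        level_of_participant = np.repeat(np.array(LEVELS), npg * n_groups)
        level_names = ["own"]

    delta = rng.normal(0.0, params.sd_a, size=(R, n_part))
    c = rng.normal(params.criterion_mean, params.criterion_sd, size=(R, n_part))
    inatt = rng.uniform(size=(R, n_part)) < params.p_inattentive

    t_phase = np.stack([np.zeros(n_part), group_hours])  # (2, n_part)
    d_latent = np.empty((R, n_part, n_levels, 2))
    for li in range(n_levels):
        if within:
            form, a, b = params.level(LEVELS[li])
            a_i = np.maximum(0.0, a + delta)  # (R, n_part)
            for ph in range(2):
                d_latent[:, :, li, ph] = np.maximum(
                    0.0, _eval_vec(form, a_i, b, t_phase[ph])
                )
        else:
            for lev in LEVELS:
                mask = level_of_participant == lev
                form, a, b = params.level(lev)
                a_i = np.maximum(0.0, a + delta[:, mask])
                for ph in range(2):
                    d_latent[:, mask, li, ph] = np.maximum(
                        0.0, _eval_vec(form, a_i, b, t_phase[ph][mask])
                    )

    n_t = design.targets_per_level_per_phase
    n_d = design.distractors_per_phase
    p_hit = norm.cdf(d_latent - c[:, :, None, None])
    p_fa = np.broadcast_to(norm.cdf(-c)[:, :, None], (R, n_part, 2)).copy()
    p_hit = np.where(inatt[:, :, None, None], 0.5, p_hit)
    p_fa = np.where(inatt[:, :, None], 0.5, p_fa)

    hits = rng.binomial(n_t, p_hit)  # (R, n_part, n_levels, 2)
    fas_shared = rng.binomial(n_d, p_fa)  # (R, n_part, 2): one draw per phase
    fas = np.broadcast_to(fas_shared[:, :, None, :], hits.shape)

    H = (hits + 0.5) / (n_t + 1.0)
    FA = (fas + 0.5) / (n_d + 1.0)
    zh, zf = norm.ppf(H), norm.ppf(FA)
    return {
        "d_prime": zh - zf,
        "criterion": -0.5 * (zh + zf),
        "hit_rate": H,
        "fa_rate": FA,
        "group_hours": group_hours,
        "group_index": group_index,
        "level_of_participant": level_of_participant,
        "level_names": level_names,
    }


def _eval_vec(form: str, a: np.ndarray, b: float, t: np.ndarray) -> np.ndarray:
    """evaluate() broadcast over participant intercepts a and delays t."""
    if form == "power":
        return a * np.power(t + 1.0, -b)
    if form == "exponential":
        return a * np.exp(-b * t)
    if form == "linear":
        return a - b * t
    if form == "logarithmic":
        return a - b * np.log(t + 1.0)
    raise ValueError(f"unknown retention form {form!r}")
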