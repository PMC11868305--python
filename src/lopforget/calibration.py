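"""Monte-Carlo calibration studies for the inference pipeline.

Two simulation studies characterise the pipeline on data with known truth:

* :func:`interaction_type1_error` — size of the level x delay-group
  interaction F-test in the split-plot ANOVA when the interaction is truly
  null. The null world keeps the level effect (deep > shallow) but makes the
  retention law flat (slope 0), so group membership shifts nothing; scores
  come from the score-level simulator and chance-level participants are
  screened out exactly as in the pipeline.
* :func:`slope_recovery` — accuracy of the retention-slope estimate b as a
  function of participants per delay group, fitting the weighted cell means
  of each simulated study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anova import mixed_anova
from .design import GenerativeParams, StudyDesign, DelayGroup
from .retention import fit
from .simulate import simulate_dprime_scores

__all__ = ["interaction_type1_error", "slope_recovery", "null_interaction_params"]


def null_interaction_params(seed: int = 0) -> GenerativeParams:
    """Generative world with a level effect but a truly null interaction.

    Flat retention (b = 0 under the power form) keeps latent d' constant over
    delay, so neither the delay main effect nor the level x delay interaction
    exists; the deep-shallow gap of 0.5 d' units is preserved.
    """
    return GenerativeParams(b_deep=0.0, b_shallow=0.0, a_deep=2.6, a_shallow=2.1,
                            seed=seed)


def interaction_type1_error(
    design: StudyDesign,
    n_sims: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    params: GenerativeParams | None = None,
) -> dict:
    """Rejection rate of the interaction test under a null interaction.

    Each replicate draws the study from the score-level simulator, drops
    chance-level participants (immediate d' <= 0 at either level, the rule
    inattentive responders trip), and runs the split-plot ANOVA on the
    delayed-phase d' scores. Returns the Monte-Carlo rejection rate with its
    binomial standard error.
    """
    if design.lop_design != "within":
        raise ValueError("calibration targets the within-participant designs")
    if params is None:
        params = null_interaction_params(seed)
    draws = simulate_dprime_scores(design, params, n_replicates=n_sims, seed=seed)
    d = draws["d_prime"]  # (n_sims, n_part, 2 levels, 2 phases)
    groups = draws["group_index"]
    n_part = d.shape[1]
    rejections = 0
    used = []
    for r in range(n_sims):
        keep = (d[r, :, :, 0] > 0).all(axis=1)
        idx = np.flatnonzero(keep)
        frame = pd.DataFrame(
            {
                "participant_id": np.repeat(idx, 2),
                "lop_condition": np.tile(["deep", "shallow"], idx.size),
                "delay_group": np.repeat(groups[idx], 2),
                "d_prime": d[r, idx, :, 1].ravel(),
            }
        )
        table = mixed_anova(frame)
        p = table.loc[table["effect"] == "lop_condition:delay_group", "p"].iloc[0]
        rejections += p < alpha
        used.append(idx.size)
    rate = rejections / n_sims
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / n_sims)),
        "mean_participants_kept": float(np.mean(used)),
        "n_participants": n_part,
    }


def slope_recovery(
    participants_per_group: tuple[int, ...] = (15, 30, 60),
    n_studies: int = 200,
    a: float = 2.5,
    b: float = 0.4,
    form: str = "power",
    seed: int = 0,
) -> pd.DataFrame:
    """Median absolute error of the slope estimate vs. group size.

    Simulates ``n_studies`` studies of the 2 x 3 within-participant geometry
    (delays 0.5/2/24 h) per group size with both levels on the same retention
    law, fits the form to the deep condition's cell means of each study, and
    summarises |b_hat - b|.
    """
    rows = []
    for size_i, npg in enumerate(participants_per_group):
        design = StudyDesign(
            lop_design="within",
            delay_groups=(DelayGroup("30min", 0.5), DelayGroup("2h", 2.0),
                          DelayGroup("24h", 24.0)),
            participants_per_group=npg,
            targets_per_level_per_phase=10,
            distractors_per_phase=40,
        )
        params = GenerativeParams(
            form_deep=form, form_shallow=form, a_deep=a, a_shallow=a,
            b_deep=b, b_shallow=b, p_inattentive=0.0, seed=seed,
        )
        draws = simulate_dprime_scores(
            design, params, n_replicates=n_studies, seed=seed + size_i
        )
        d = draws["d_prime"]  # (n_studies, n_part, 2, 2)
        groups = draws["group_index"]
        hours = np.array([g.hours for g in design.delay_groups])
        errors = np.empty(n_studies)
        for r in range(n_studies):
            deep = d[r, :, 0, :]  # (n_part, phases)
            t_cells = [0.0] + list(hours)
            means = [deep[:, 0].mean()] + [
                deep[groups == g, 1].mean() for g in range(3)
            ]
            ns = [deep.shape[0]] + [int((groups == g).sum()) for g in range(3)]
            f = fit(form, t_cells, means, weights=ns)
            errors[r] = abs(f.b - b)
        rows.append(
            {
                "participants_per_group": npg,
                "n_studies": n_studies,
                "median_abs_error_b": float(np.median(errors)),
                "mean_abs_error_b": float(np.mean(errors)),
            }
        )
    return pd.DataFrame(rows)
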