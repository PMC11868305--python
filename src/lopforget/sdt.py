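"""Signal-detection scoring of old/new recognition trial tables.

Per participant x encoding level x test phase, hits ("old" to targets) and
false alarms ("old" to distractors) are counted, rates are corrected with the
log-linear adjustment (add 0.5 to each count, 1 to each trial total) so no
rate sits at 0 or 1, and equal-variance SDT indices are computed:

    d' = z(H) - z(FA)          (discriminability)
    c  = -(z(H) + z(FA)) / 2   (criterion location; positive = conservative)

Participant exclusion follows the study's screening rules: chance-level
immediate discrimination (d' <= 0 at either level) and immediate hit or
false-alarm rates more than 2.5 sample SDs from the sample mean of that rate.
In within-participant designs the distractors of a test phase are shared
between levels (rows carry lop_condition "shared") and count toward both
levels' false-alarm rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RecognitionCounts",
    "SDTScore",
    "tabulate_counts",
    "corrected_rates",
    "score",
    "score_trials",
    "exclude_participants",
    "summarize_cells",
]

CORRECTION_MODES = ("loglinear_all", "loglinear_extremes_only")


@dataclass(frozen=True)
class RecognitionCounts:
    n_targets: int
    n_distractors: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if self.n_targets <= 0 or self.n_distractors <= 0:
            raise ValueError("cell has zero targets or zero distractors")
        if not 0 <= self.hits <= self.n_targets:
            raise ValueError("hits must lie in [0, n_targets]")
        if not 0 <= self.false_alarms <= self.n_distractors:
            raise ValueError("false_alarms must lie in [0, n_distractors]")


@dataclass(frozen=True)
class SDTScore:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float


def tabulate_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Count hits and false alarms per (participant, level, phase).

    Distractor rows with lop_condition "shared" (within-participant designs)
    are counted toward every level present in that participant's phase block.
    Nothing is dropped: target and distractor rows partition each block.
    """
    required = {"participant_id", "lop_condition", "phase", "delay_hours",
                "item_role", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")

    rows = []
    for (pid, phase), block in trials.groupby(["participant_id", "phase"], sort=False):
        targets = block[block["item_role"] == "target"]
        distractors = block[block["item_role"] == "distractor"]
        levels = sorted(targets["lop_condition"].unique())
        delay = float(block["delay_hours"].iloc[0])
        group = block["delay_group"].iloc[0] if "delay_group" in block else ""
        for level in levels:
            tgt = targets[targets["lop_condition"] == level]
            dis = distractors[distractors["lop_condition"].isin([level, "shared"])]
            if len(tgt) == 0 or len(dis) == 0:
                raise ValueError(
                    f"cell ({pid!r}, {level!r}, {phase!r}) has zero targets "
                    "or zero distractors"
                )
            rows.append(
                {
                    "participant_id": pid,
                    "lop_condition": level,
                    "phase": phase,
                    "delay_group": group,
                    "delay_hours": delay,
                    "n_targets": len(tgt),
                    "hits": int((tgt["response"] == "old").sum()),
                    "n_distractors": len(dis),
                    "false_alarms": int((dis["response"] == "old").sum()),
                }
            )
    return pd.DataFrame(rows)


def corrected_rates(
    counts: RecognitionCounts, mode: str = "loglinear_all"
) -> tuple[float, float]:
    """Hit and false-alarm rates after the log-linear correction.

    ``loglinear_all`` (default) applies (x + 0.5)/(n + 1) to every cell;
    ``loglinear_extremes_only`` applies it only where the raw rate is 0 or 1.
    Either way the returned rates are strictly inside (0, 1).
    """
    if mode not in CORRECTION_MODES:
        raise ValueError(f"unknown correction mode {mode!r}")

    def one(x: int, n: int) -> float:
        raw = x / n
        if mode == "loglinear_all" or raw in (0.0, 1.0):
            return (x + 0.5) / (n + 1.0)
        return raw

    return one(counts.hits, counts.n_targets), one(
        counts.false_alarms, counts.n_distractors
    )


def score(hit_rate: float, fa_rate: float) -> SDTScore:
    """d' and criterion from corrected rates (both strictly in (0, 1))."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must be strictly inside (0, 1); correct first")
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return SDTScore(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=float(zh - zf),
        criterion=float(-0.5 * (zh + zf)),
    )


def score_trials(
    trials: pd.DataFrame, correction: str = "loglinear_all"
) -> pd.DataFrame:
    """Trial table -> per (participant, level, phase) SDT scores."""
    counts = tabulate_counts(trials)
    h = np.empty(len(counts))
    fa = np.empty(len(counts))
    for i, row in enumerate(counts.itertuples(index=False)):
        h[i], fa[i] = corrected_rates(
            RecognitionCounts(row.n_targets, row.n_distractors, row.hits,
                              row.false_alarms),
            mode=correction,
        )
    out = counts.copy()
    out["hit_rate"] = h
    out["fa_rate"] = fa
    zh, zf = norm.ppf(h), norm.ppf(fa)
    out["d_prime"] = zh - zf
    out["criterion"] = -0.5 * (zh + zf)
    return out


def exclude_participants(
    scores: pd.DataFrame, sd_threshold: float = 2.5
) -> tuple[list, pd.DataFrame]:
    """Apply the immediate-phase screening rules.

    A participant is excluded when immediate d' <= 0 at either level
    (``chance_level``) or when an immediate hit or false-alarm rate lies more
    than ``sd_threshold`` sample SDs from that rate's sample mean across all
    participants, pooled over levels (``rate_outlier``). With fewer than 3
    participants the SD screen is skipped with a warning; a zero-SD rate
    flags nobody.

    Returns (kept participant ids, exclusion table with reasons).
    """
    imm = scores[scores["phase"] == "immediate"]
    if imm.empty:
        raise ValueError("no immediate-phase scores; cannot screen")
    all_ids = list(dict.fromkeys(scores["participant_id"]))
    missing = set(all_ids) - set(imm["participant_id"])
    if missing:
        raise ValueError(f"participants lack immediate scores: {sorted(missing)}")

    excl: list[dict] = []
    chance = imm.loc[imm["d_prime"] <= 0, ["participant_id", "lop_condition", "d_prime"]]
    for row in chance.itertuples(index=False):
        excl.append(
            {
                "participant_id": row.participant_id,
                "reason": "chance_level",
                "detail": f"immediate d'={row.d_prime:.4f} ({row.lop_condition})",
            }
        )

    n_part = imm["participant_id"].nunique()
    if n_part < 3:
        warnings.warn(
            "fewer than 3 participants: 2.5-SD rate screen skipped", stacklevel=2
        )
    else:
        for rate in ("hit_rate", "fa_rate"):
            vals = imm[rate].to_numpy(float)
            mu, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                continue
            z = (vals - mu) / sd
            for pid, zi in zip(imm["participant_id"], z):
                if abs(zi) > sd_threshold:
                    excl.append(
                        {
                            "participant_id": pid,
                            "reason": "rate_outlier",
                            "detail": f"immediate {rate} at {zi:+.2f} SD",
                        }
                    )
    excl_df = pd.DataFrame(
        excl, columns=["participant_id", "reason", "detail"]
    ).drop_duplicates(ignore_index=True)
    dropped = set(excl_df["participant_id"])
    kept = [p for p in all_ids if p not in dropped]
    return kept, excl_df


def summarize_cells(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-cell d' summaries in the shape of the published summary table.

    Cells are level x delay: the immediate phase pools all delay groups at
    t = 0; each delayed cell is one delay group. Emits n, mean and
    SE = SD/sqrt(n); single-score cells get a missing SE; empty cells are
    omitted (nothing to summarise).
    """
    rows = []
    for (condition, phase, delay), sub in scores.groupby(
        ["lop_condition", "phase", "delay_hours"], sort=True
    ):
        label = "immediate" if phase == "immediate" else str(sub["delay_group"].iloc[0])
        d = sub["d_prime"].to_numpy(float)
        n = len(d)
        rows.append(
            {
                "condition": condition,
                "label": label,
                "t_hours": float(delay),
                "mean": float(d.mean()),
                "se": float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "n": n,
            }
        )
    out = pd.DataFrame(rows).sort_values(["condition", "t_hours"], kind="stable")
    return out.reset_index(drop=True)
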