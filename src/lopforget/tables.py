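"""Published cell summaries of the three levels-of-processing experiments.

These are the printed per-cell recognition d' summaries (mean, SE, n) used as
inputs for summary-level refits of the retention functions: the immediate cell
pools all delay groups (every participant takes the immediate test), while
each delayed cell is one delay group. Sample sizes are post-exclusion for
experiments 1 and 2; experiment 3 does not attribute its six exclusions to
delay groups, so the pre-exclusion 20 per cell (60 pooled immediate) is used
and flagged by the pipeline.
"""

from __future__ import annotations

import pandas as pd

_COLS = ["condition", "label", "t_hours", "mean", "se", "n"]


def _cells(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLS)


#: Experiment 1 (deep = sentence, shallow = rhyme; delays 0.5/2/24 h).
EXP1_CELLS = _cells(
    [
        ("deep", "immediate", 0.0, 2.61, 0.07, 86),
        ("deep", "30min", 0.5, 1.69, 0.10, 30),
        ("deep", "2h", 2.0, 1.59, 0.11, 28),
        ("deep", "24h", 24.0, 1.01, 0.11, 28),
        ("shallow", "immediate", 0.0, 2.10, 0.06, 86),
        ("shallow", "30min", 0.5, 1.21, 0.10, 30),
        ("shallow", "2h", 2.0, 1.32, 0.09, 28),
        ("shallow", "24h", 24.0, 0.61, 0.10, 28),
    ]
)

#: Experiment 2 (deep = sentence, shallow = consonant-vowel structure).
EXP2_CELLS = _cells(
    [
        ("deep", "immediate", 0.0, 2.58, 0.07, 72),
        ("deep", "30min", 0.5, 1.67, 0.17, 24),
        ("deep", "2h", 2.0, 1.34, 0.11, 24),
        ("deep", "24h", 24.0, 0.93, 0.10, 24),
        ("shallow", "immediate", 0.0, 1.83, 0.09, 72),
        ("shallow", "30min", 0.5, 1.02, 0.16, 24),
        ("shallow", "2h", 2.0, 0.84, 0.11, 24),
        ("shallow", "24h", 24.0, 0.59, 0.12, 24),
    ]
)

#: Experiment 3 (between-participants; delays 0.5/2/6 h; pre-exclusion ns).
EXP3_CELLS = _cells(
    [
        ("deep", "immediate", 0.0, 2.83, 0.08, 60),
        ("deep", "30min", 0.5, 1.63, 0.11, 20),
        ("deep", "2h", 2.0, 1.56, 0.13, 20),
        ("deep", "6h", 6.0, 1.43, 0.12, 20),
        ("shallow", "immediate", 0.0, 2.11, 0.06, 60),
        ("shallow", "30min", 0.5, 1.22, 0.15, 20),
        ("shallow", "2h", 2.0, 0.96, 0.12, 20),
        ("shallow", "6h", 6.0, 0.66, 0.08, 20),
    ]
)

CELL_TABLES = {"exp1": EXP1_CELLS, "exp2": EXP2_CELLS, "exp3": EXP3_CELLS}

#: Observed mean delays (hours) per delayed group, available as an alternative
#: time convention ("actual") to the nominal delays; experiment 3 values are
#: averaged over its two between-participant conditions.
ACTUAL_DELAYS = {
    "exp1": {"30min": 32.63 / 60.0, "2h": 1.95, "24h": 23.95},
    "exp2": {"30min": 35.80 / 60.0, "2h": 1.92, "24h": 23.84},
    "exp3": {"30min": 34.5 / 60.0, "2h": 2.01, "6h": 5.98},
}


def with_actual_delays(cells: pd.DataFrame, experiment: str) -> pd.DataFrame:
    """Replace nominal t_hours with the observed mean delays."""
    actual = ACTUAL_DELAYS[experiment]
    out = cells.copy()
    out["t_hours"] = [actual.get(lbl, t) for lbl, t in zip(out["label"], out["t_hours"])]
    return out
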