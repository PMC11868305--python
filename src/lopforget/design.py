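"""Study designs and generative parameters for old/new recognition experiments.

A study crosses a levels-of-processing (LOP) manipulation (deep vs. shallow
orienting task) with a between-participants retention-interval factor. Every
participant takes an immediate recognition test (t = 0) on half of the studied
targets and a delayed test on the other half against fresh distractors, so no
item is retrieved twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

LEVELS = ("deep", "shallow")
RETENTION_FORMS = ("linear", "power", "exponential", "logarithmic")

LopDesign = Literal["within", "between"]


@dataclass(frozen=True)
class DelayGroup:
    """A between-participants retention-interval condition."""

    label: str
    hours: float

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ValueError(f"nominal delay must be >= 0, got {self.hours}")


@dataclass(frozen=True)
class StudyDesign:
    """Geometry of one experiment.

    Parameters
    ----------
    lop_design
        ``"within"``: every participant performs both orienting tasks
        (items split between levels); ``"between"``: each participant is
        assigned one level.
    delay_groups
        Delayed-test conditions; the immediate test at t = 0 is implicit and
        always present.
    participants_per_group
        Participants per delay group (per LOP condition when between).
    targets_per_level_per_phase
        Studied items per level tested in each phase (10 in the
        within-participant designs, 20 in the between design).
    distractors_per_phase
        New items mixed into each test phase (40 throughout).
    encoding_time_limit_ms
        Response window of the paced orienting task; recognition RTs are
        truncated here too.
    """

    lop_design: LopDesign
    delay_groups: tuple[DelayGroup, ...]
    participants_per_group: int
    targets_per_level_per_phase: int
    distractors_per_phase: int
    encoding_time_limit_ms: int = 5000

    def __post_init__(self) -> None:
        if self.lop_design not in ("within", "between"):
            raise ValueError(f"unknown lop_design {self.lop_design!r}")
        labels = [g.label for g in self.delay_groups]
        if len(set(labels)) != len(labels):
            raise ValueError("delay group labels must be unique")
        hours = [g.hours for g in self.delay_groups]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("nominal delays must be strictly increasing")
        if self.participants_per_group <= 0:
            raise ValueError("participants_per_group must be positive")
        if self.targets_per_level_per_phase <= 0:
            raise ValueError("targets_per_level_per_phase must be positive")
        if self.distractors_per_phase <= 0:
            raise ValueError("distractors_per_phase must be positive")
        if self.encoding_time_limit_ms <= 0:
            raise ValueError("encoding_time_limit_ms must be positive")

    @property
    def n_levels_per_participant(self) -> int:
        return 2 if self.lop_design == "within" else 1

    @property
    def targets_per_phase(self) -> int:
        return self.targets_per_level_per_phase * self.n_levels_per_participant


@dataclass(frozen=True)
class GenerativeParams:
    """Latent parameters of the bi-normal (equal-variance SDT) simulator.

    Each participant i draws an intercept deviation shared across levels,
    a_i(level) = a_level + delta_i with delta_i ~ N(0, sd_a^2) (the realised
    intercept is truncated at 0), and an absolute evidence criterion
    c_i ~ N(criterion_mean, criterion_sd^2). True discriminability at delay t
    is d'(t) = max(0, f(t; a_i, b_level)) under the level's retention form.
    Target evidence ~ N(d', 1), distractor evidence ~ N(0, 1); the response is
    "old" iff evidence exceeds c_i. Inattentive participants (probability
    p_inattentive) respond "old" with probability one half on every trial.
    RTs are lognormal in log-ms, truncated at the encoding time limit.
    """

    form_deep: str = "power"
    form_shallow: str = "power"
    a_deep: float = 2.6
    a_shallow: float = 2.1
    b_deep: float = 0.36
    b_shallow: float = 0.44
    sd_a: float = 0.45
    criterion_mean: float = 1.25
    criterion_sd: float = 0.30
    rt_mu_deep: float = 7.91
    rt_mu_shallow: float = 7.58
    rt_sigma: float = 0.40
    p_inattentive: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("form_deep", "form_shallow"):
            if getattr(self, name) not in RETENTION_FORMS:
                raise ValueError(
                    f"{name} must be one of {RETENTION_FORMS}, got {getattr(self, name)!r}"
                )
        if self.a_deep <= 0 or self.a_shallow <= 0:
            raise ValueError("latent intercepts a_* must be > 0")
        if self.sd_a < 0 or self.criterion_sd < 0 or self.rt_sigma < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if not 0 <= self.p_inattentive < 1:
            raise ValueError("p_inattentive must be in [0, 1)")

    def level(self, lop: str) -> tuple[str, float, float]:
        """(form, a, b) for one LOP condition."""
        if lop == "deep":
            return self.form_deep, self.a_deep, self.b_deep
        if lop == "shallow":
            return self.form_shallow, self.a_shallow, self.b_shallow
        raise ValueError(f"unknown LOP condition {lop!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _groups(*pairs: tuple[str, float]) -> tuple[DelayGroup, ...]:
    return tuple(DelayGroup(label, hours) for label, hours in pairs)


#: 2 (LOP, within) x 3 (delay) design: 30 participants per delay group,
#: 10 targets per level per phase, 40 distractors per phase.
EXP1_DESIGN = StudyDesign(
    lop_design="within",
    delay_groups=_groups(("30min", 0.5), ("2h", 2.0), ("24h", 24.0)),
    participants_per_group=30,
    targets_per_level_per_phase=10,
    distractors_per_phase=40,
)

#: Same geometry with 24 participants per delay group (structural shallow task).
EXP2_DESIGN = StudyDesign(
    lop_design="within",
    delay_groups=_groups(("30min", 0.5), ("2h", 2.0), ("24h", 24.0)),
    participants_per_group=24,
    targets_per_level_per_phase=10,
    distractors_per_phase=40,
)

#: Fully between-participants 2 x 3 design, delays up to 6 h, 20 per cell.
EXP3_DESIGN = StudyDesign(
    lop_design="between",
    delay_groups=_groups(("30min", 0.5), ("2h", 2.0), ("6h", 6.0)),
    participants_per_group=20,
    targets_per_level_per_phase=20,
    distractors_per_phase=40,
)

DESIGNS = {"exp1": EXP1_DESIGN, "exp2": EXP2_DESIGN, "exp3": EXP3_DESIGN}
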