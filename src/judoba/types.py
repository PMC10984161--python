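"""Core domain types for contest accelerometry.

The unit of observation is one athlete's 5-minute simulated contest,
recorded by a belt-worn triaxial accelerometer and reduced to 3-second
epochs of activity counts on the vertical (axis 1), mediolateral (axis 2)
and anteroposterior (axis 3) axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

SEXES = ("male", "female")
WEIGHT_CLASSES = ("light", "middle", "heavy")
AXES = ("vertical", "mediolateral", "anteroposterior")

#: Borg rating-of-perceived-exertion scale bounds.
RPE_MIN, RPE_MAX = 6.0, 20.0


class ConfigurationError(ValueError):
    """A cohort or design parameter is invalid; the message names the field."""


class TraceFormatError(ValueError):
    """An epoch file or in-memory trace violates the epoch-CSV contract."""


def predicted_hr_max(age_years: float) -> float:
    """Age-predicted maximal heart rate, 208 - 0.7 x age (beats/min)."""
    return 208.0 - 0.7 * age_years


class EpochRecord(NamedTuple):
    """Counts accumulated over one epoch, starting at ``t_start`` seconds."""

    t_start: int
    axis1: int  # vertical
    axis2: int  # mediolateral
    axis3: int  # anteroposterior


@dataclass(frozen=True)
class ContestDesign:
    """Timing structure of a simulated contest.

    A contest is an alternating sequence of effort bouts (uniform length
    between ``effort_min_s`` and ``effort_max_s`` seconds) and fixed
    ``break_s``-second breaks, truncated at ``contest_seconds``. Breaks are
    recorded, not excised: during a break the athlete still moves at
    ``break_intensity_fraction`` of the effort count rate.
    """

    contest_seconds: int = 300
    epoch_seconds: int = 3
    effort_min_s: float = 20.0
    effort_max_s: float = 30.0
    break_s: float = 10.0
    break_intensity_fraction: float = 0.15
    #: coefficient of variation of per-epoch axis counts around the
    #: athlete's target rate (within-contest noise; not reported by
    #: summary statistics, so a modelling choice).
    epoch_cv: float = 0.25

    def validate(self) -> None:
        if self.contest_seconds <= 0 or self.epoch_seconds <= 0:
            raise ConfigurationError("contest_seconds and epoch_seconds must be positive")
        if self.contest_seconds % self.epoch_seconds != 0:
            raise ConfigurationError(
                "contest_seconds must be divisible by epoch_seconds "
                f"(got {self.contest_seconds} / {self.epoch_seconds})"
            )
        if self.effort_min_s > self.effort_max_s:
            raise ConfigurationError("effort_min_s must not exceed effort_max_s")
        if self.effort_min_s <= 0:
            raise ConfigurationError("effort_min_s must be positive")
        if self.effort_min_s > self.contest_seconds:
            raise ConfigurationError("effort_min_s exceeds contest_seconds")
        if self.break_s <= 0:
            raise ConfigurationError("break_s must be positive")
        if not 0.0 <= self.break_intensity_fraction <= 1.0:
            raise ConfigurationError("break_intensity_fraction must be in [0, 1]")
        if self.epoch_cv < 0:
            raise ConfigurationError("epoch_cv must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.contest_seconds // self.epoch_seconds


@dataclass(frozen=True)
class GroupSpec:
    """Target distribution of one sex x weight cell of the cohort.

    Means and SDs are per-contest summaries: vector-magnitude counts per
    minute (a.u./cpm), axis shares (% of the summed per-axis cpm), peak
    contest heart rate (b/min), blood lactate one minute post-contest
    (mmol/L), Borg 6-20 RPE, and age (years).
    """

    sex: str
    weight_class: str
    n_athletes: int
    vm_mean: float
    vm_sd: float
    axis_share_means: tuple[float, float, float]
    axis_share_sds: tuple[float, float, float]
    hr_mean: float
    hr_sd: float
    bla_mean: float
    bla_sd: float
    rpe_mean: float
    rpe_sd: float
    age_mean: float
    age_sd: float

    @property
    def label(self) -> str:
        """Conventional cell label, e.g. ``ML`` for male lightweight."""
        return self.sex[0].upper() + self.weight_class[0].upper()

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ConfigurationError(
                f"weight_class must be one of {WEIGHT_CLASSES}, got {self.weight_class!r}"
            )
        if self.n_athletes < 2:
            raise ConfigurationError("n_athletes must be at least 2")
        for name in ("vm_sd", "hr_sd", "bla_sd", "rpe_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if len(self.axis_share_means) != 3 or len(self.axis_share_sds) != 3:
            raise ConfigurationError("axis_share_means and axis_share_sds need 3 entries")
        if any(s < 0 for s in self.axis_share_sds):
            raise ConfigurationError("axis_share_sds must be non-negative")
        if any(m <= 0 for m in self.axis_share_means):
            raise ConfigurationError("axis_share_means must be positive")
        total = sum(self.axis_share_means)
        if abs(total - 100.0) > 0.5:
            raise ConfigurationError(
                f"axis_share_means must sum to 100 +/- 0.5, got {total:.2f}"
            )
        if not (RPE_MIN <= self.rpe_mean <= RPE_MAX):
            raise ConfigurationError(
                f"rpe_mean must lie on the Borg scale [{RPE_MIN:g}, {RPE_MAX:g}]"
            )
        if self.vm_mean <= 0:
            raise ConfigurationError("vm_mean must be positive")


@dataclass(frozen=True)
class AthleteProfile:
    athlete_id: str
    sex: str
    weight_class: str

    @property
    def group(self) -> str:
        return self.sex[0].upper() + self.weight_class[0].upper()


@dataclass(frozen=True)
class PhysiologyRecord:
    """Per-athlete physiological certification measures."""

    hr_max_contest: float  # peak HR during the contest, b/min
    bla: float             # blood lactate 1 min post-contest, mmol/L
    rpe: float             # Borg 6-20 rating of perceived exertion
    age: float             # years

    @property
    def hr_max_predicted(self) -> float:
        return predicted_hr_max(self.age)

    @property
    def pct_hrmax(self) -> float:
        """Contest peak HR as a percentage of the age-predicted maximum."""
        return 100.0 * self.hr_max_contest / self.hr_max_predicted


@dataclass
class ContestTrace:
    """One athlete's epoch-level triaxial count record.

    ``counts`` is an ``(n_epochs, 3)`` integer array in the fixed axis
    order vertical / mediolateral / anteroposterior; ``t_start`` gives each
    epoch's offset in seconds and ``phase_labels`` marks epochs as
    ``"effort"`` or ``"break"`` (empty when the schedule is unknown, e.g.
    traces read from disk).
    """

    athlete_id: str
    t_start: np.ndarray
    counts: np.ndarray
    phase_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype="U6"))

    def __post_init__(self) -> None:
        self.t_start = np.asarray(self.t_start, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise TraceFormatError("counts must be an (n_epochs, 3) array")
        if len(self.t_start) != len(self.counts):
            raise TraceFormatError("t_start and counts lengths differ")
        if (self.counts < 0).any():
            raise TraceFormatError("counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def epoch_seconds(self) -> int:
        if self.n_epochs < 2:
            raise TraceFormatError("cannot infer epoch length from fewer than 2 epochs")
        steps = np.diff(self.t_start)
        if len(set(steps.tolist())) != 1:
            raise TraceFormatError("non-uniform epoch spacing")
        return int(steps[0])

    @property
    def contest_seconds(self) -> int:
        return self.n_epochs * self.epoch_seconds

    @property
    def epochs(self) -> list[EpochRecord]:
        return [
            EpochRecord(int(t), int(a), int(b), int(c))
            for t, (a, b, c) in zip(self.t_start, self.counts)
        ]

    def __iter__(self) -> Iterator[EpochRecord]:
        return iter(self.epochs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContestTrace):
            return NotImplemented
        return (
            self.athlete_id == other.athlete_id
            and np.array_equal(self.t_start, other.t_start)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class ContestSummary:
    """Per-athlete contest outcomes in the units the analysis compares.

    ``vm_cpm`` is the mean over contest minutes of the summed per-epoch
    vector magnitudes; ``axis_cpm`` are per-axis counts per minute and
    ``axis_pct`` each axis's share of their sum. Physiological fields are
    ``nan`` when the trace was summarised without a physiology record.
    """

    athlete_id: str
    vm_cpm: float
    axis_cpm: tuple[float, float, float]
    axis_pct: tuple[float, float, float]
    hr_max_contest: float = float("nan")
    pct_hrmax: float = float("nan")
    bla: float = float("nan")
    rpe: float = float("nan")
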