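"""Seeded synthetic cohort generator.

The study design this emulates: six sex x weight cells of athletes, each
fighting one 5-minute simulated contest recorded as 3-second triaxial
count epochs, with peak heart rate, post-contest blood lactate and Borg
RPE collected alongside. Only per-contest summary distributions (cell
means and SDs) are published, so the generator is calibrated to those
targets and the within-contest structure is modelled:

* contests alternate effort bouts (uniform 20-30 s) with 10 s breaks;
* per-epoch axis counts are gamma-distributed around the athlete's
  target rate (non-negative and right-skewed, like count data), with
  breaks emitting a fixed fraction of the effort rate;
* each athlete's trace is rescaled so its pre-rounding contest vector
  magnitude equals the athlete's drawn target, making cohort calibration
  exact up to integer rounding;
* per-athlete axis shares are drawn logistic-normally around the cell
  target so they stay positive and sum to 100 exactly.

Randomness derives from one root seed via per-athlete child streams
(``SeedSequence(seed, spawn_key=(group_index, athlete_index))``), so
enlarging one cell never perturbs another athlete's data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .types import (
    RPE_MAX,
    RPE_MIN,
    AthleteProfile,
    ConfigurationError,
    ContestDesign,
    ContestTrace,
    GroupSpec,
    PhysiologyRecord,
)

__all__ = [
    "generate_cohort",
    "generate_contest_trace",
    "generate_physiology",
    "load_cohort_config",
    "sample_effort_pause_schedule",
    "table2_cohort_path",
]

#: lower bound for sampled athlete ages (adult competitors).
AGE_MIN = 18.0


def table2_cohort_path() -> Path:
    """Path to the bundled six-cell cohort configuration.

    The bundled file encodes the published group means and SDs for an
    n=16-per-cell cohort of national/international judo athletes.
    """
    return Path(str(resources.files("judoba").joinpath("data/table2_cohort.yaml")))


def load_cohort_config(path: str | Path) -> list[GroupSpec]:
    """Load and validate a cohort configuration from YAML or JSON.

    The file holds a ``groups`` list whose entries mirror ``GroupSpec``
    field names (``axis_share_means`` / ``axis_share_sds`` as 3-lists in
    vertical, mediolateral, anteroposterior order).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ConfigurationError(f"cohort config {path} must contain a 'groups' list")
    specs = []
    for entry in raw["groups"]:
        try:
            spec = GroupSpec(
                sex=entry["sex"],
                weight_class=entry["weight_class"],
                n_athletes=int(entry["n_athletes"]),
                vm_mean=float(entry["vm_mean"]),
                vm_sd=float(entry["vm_sd"]),
                axis_share_means=tuple(float(v) for v in entry["axis_share_means"]),
                axis_share_sds=tuple(float(v) for v in entry["axis_share_sds"]),
                hr_mean=float(entry["hr_mean"]),
                hr_sd=float(entry["hr_sd"]),
                bla_mean=float(entry["bla_mean"]),
                bla_sd=float(entry["bla_sd"]),
                rpe_mean=float(entry["rpe_mean"]),
                rpe_sd=float(entry["rpe_sd"]),
                age_mean=float(entry["age_mean"]),
                age_sd=float(entry["age_sd"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"cohort config group is missing field {exc}") from exc
        spec.validate()
        specs.append(spec)
    if not specs:
        raise ConfigurationError("cohort config defines no groups")
    return specs


def sample_effort_pause_schedule(
    design: ContestDesign, rng: np.random.Generator
) -> np.ndarray:
    """Sample per-epoch phase labels for one contest.

    Effort bouts are uniform on [effort_min_s, effort_max_s], rounded to
    whole epochs; every break lasts exactly ``break_s`` (rounded to whole
    epochs); the alternation starts with effort and is truncated at the
    contest end. Returns an array of ``"effort"`` / ``"break"`` labels of
    length ``design.n_epochs``.
    """
    design.validate()
    n = design.n_epochs
    break_epochs = max(1, round(design.break_s / design.epoch_seconds))
    labels: list[str] = []
    while len(labels) < n:
        bout_s = rng.uniform(design.effort_min_s, design.effort_max_s)
        bout_epochs = max(1, round(bout_s / design.epoch_seconds))
        labels.extend(["effort"] * bout_epochs)
        labels.extend(["break"] * break_epochs)
    return np.array(labels[:n], dtype="U6")


def _truncnorm_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """One draw from a normal truncated to [lower, upper]; sd=0 gives the
    clipped mean."""
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def truncnorm_mean(
    mean: float, sd: float, lower: float = -np.inf, upper: float = np.inf
) -> float:
    """Expected value of the truncated normal the generator draws from."""
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def generate_physiology(spec: GroupSpec, rng: np.random.Generator) -> PhysiologyRecord:
    """Draw one athlete's physiological record from the cell targets.

    Heart rate and lactate are truncated below at zero, RPE to the Borg
    6-20 scale, and age at 18 years (adult competitors).
    """
    hr = _truncnorm_draw(rng, spec.hr_mean, spec.hr_sd, lower=0.0)
    bla = _truncnorm_draw(rng, spec.bla_mean, spec.bla_sd, lower=0.0)
    rpe = _truncnorm_draw(rng, spec.rpe_mean, spec.rpe_sd, lower=RPE_MIN, upper=RPE_MAX)
    age = _truncnorm_draw(rng, spec.age_mean, spec.age_sd, lower=AGE_MIN)
    return PhysiologyRecord(hr_max_contest=hr, bla=bla, rpe=rpe, age=age)


def _draw_axis_shares(
    means_pct: Sequence[float], sds_pct: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Logistic-normal draw of one athlete's axis shares (fractions summing
    to 1).

    Log-composition perturbations of scale sd/mean reproduce the target
    per-axis SDs to first order while keeping the composition closed.
    """
    p = np.asarray(means_pct, dtype=float)
    p = p / p.sum()
    sigma = np.asarray(sds_pct, dtype=float) / 100.0 / p
    z = np.log(p) + rng.normal(0.0, 1.0, size=3) * sigma
    w = np.exp(z - z.max())
    return w / w.sum()


def generate_contest_trace(
    athlete_id: str,
    vm_cpm_target: float,
    axis_shares: Sequence[float],
    design: ContestDesign,
    rng: np.random.Generator,
) -> ContestTrace:
    """Simulate one contest trace hitting a per-athlete VM target.

    The target epoch count vector points along ``axis_shares``; its norm
    is set so the contest total of per-epoch vector magnitudes equals
    ``vm_cpm_target * contest_minutes`` given the realised effort/break
    schedule. Gamma noise (CV ``design.epoch_cv``) perturbs every epoch
    and axis independently, after which the whole trace is rescaled so
    the pre-rounding contest VM matches the target exactly — noise then
    shapes the trace without biasing the athlete's summary.
    """
    labels = sample_effort_pause_schedule(design, rng)
    shares = np.asarray(axis_shares, dtype=float)
    if shares.min() < 0 or shares.sum() <= 0:
        raise ConfigurationError("axis shares must be non-negative with positive sum")
    shares = shares / shares.sum()

    weights = np.where(labels == "effort", 1.0, design.break_intensity_fraction)
    total_vm_target = vm_cpm_target * design.contest_seconds / 60.0
    weight_sum = weights.sum()
    if weight_sum == 0:  # all-break contest with zero break intensity
        lam = np.zeros((design.n_epochs, 3))
    else:
        effort_epoch_vm = total_vm_target / weight_sum
        unit = shares / np.linalg.norm(shares)
        lam = weights[:, None] * effort_epoch_vm * unit[None, :]

    cv = design.epoch_cv
    if cv > 0:
        shape = 1.0 / cv**2
        noisy = np.where(lam > 0, rng.gamma(shape, 1.0, size=lam.shape) * (lam / shape), 0.0)
    else:
        noisy = lam
    realized_vm = np.sqrt((noisy**2).sum(axis=1)).sum()
    if realized_vm > 0 and total_vm_target > 0:
        noisy *= total_vm_target / realized_vm
    counts = np.rint(noisy).astype(np.int64)
    counts[counts < 0] = 0

    t_start = np.arange(design.n_epochs, dtype=np.int64) * design.epoch_seconds
    return ContestTrace(
        athlete_id=athlete_id, t_start=t_start, counts=counts, phase_labels=labels
    )


def generate_cohort(
    config: Sequence[GroupSpec],
    design: ContestDesign | None = None,
    seed: int | None = None,
) -> list[tuple[AthleteProfile, ContestTrace, PhysiologyRecord]]:
    """Generate a full synthetic cohort, one contest per athlete.

    All configuration is validated before anything is generated, so a bad
    cell raises without partial output. The same ``(config, design,
    seed)`` triple always yields bit-identical traces.
    """
    if seed is None:
        raise ConfigurationError("seed is required for cohort generation")
    if not config:
        raise ConfigurationError("cohort config is empty")
    design = design or ContestDesign()
    design.validate()
    for spec in config:
        spec.validate()

    cohort = []
    for gi, spec in enumerate(config):
        for ai in range(spec.n_athletes):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(gi, ai))
            )
            athlete_id = f"{spec.label}{ai + 1:03d}"
            profile = AthleteProfile(
                athlete_id=athlete_id, sex=spec.sex, weight_class=spec.weight_class
            )
            vm_target = _truncnorm_draw(rng, spec.vm_mean, spec.vm_sd, lower=0.0)
            shares = _draw_axis_shares(spec.axis_share_means, spec.axis_share_sds, rng)
            trace = generate_contest_trace(athlete_id, vm_target, shares, design, rng)
            physio = generate_physiology(spec, rng)
            cohort.append((profile, trace, physio))
    return cohort
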