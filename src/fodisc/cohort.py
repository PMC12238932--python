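"""Synthetic study cohorts for the pitch-discrimination task.

The study population is a 2×2 design — group (control vs. hyperfunctional
voice disorder, HVD) × singer status — with unbalanced cells.  The default
cell specifications carry the published composition: cell sizes (17
non-singers and 43 singers per group, 120 total), sex counts (5 male per
cell), age means±SDs, and per-cell threshold means±SDs, which here act as
the generative moments of each participant's true JND.

Each participant's true JND is drawn from a shifted gamma distribution
(floor 2 cents) whose mean and SD are moment-matched to the cell's values:
positive support and right skew are the realistic shape for individual
pitch-acuity variability, and only the first two moments are constrained.
Ages are normal, truncated at 18 (adult cohort).  Age does not influence
the generative JND by default — the study found no age effect — but an
optional linear age slope is available for power exploration.

``generate_study`` builds a calibrated observer per participant and runs a
full adaptive session, yielding a participant table ready for the stats
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from fodisc.observer import calibrate
from fodisc.staircase import StaircaseConfig, run_session

JND_FLOOR_CENTS = 2.0
MIN_AGE_YR = 18.0
#: published average catch-trial accuracies per group
CATCH_ACCURACY_TARGETS = {"control": 0.94, "HVD": 0.95}


@dataclass(frozen=True)
class CellSpec:
    """Generative specification of one group × singer-status cell."""

    group: str  # "control" | "HVD"
    singer: bool
    n: int
    n_male: int
    age_mean_yr: float
    age_sd_yr: float
    jnd_mean_cents: float
    jnd_sd_cents: float
    age_slope_cents_per_yr: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("control", "HVD"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.n_male <= self.n:
            raise ValueError("n_male must be between 0 and n")
        if self.age_sd_yr <= 0 or self.jnd_sd_cents <= 0:
            raise ValueError("SDs must be positive")
        if self.jnd_mean_cents <= JND_FLOOR_CENTS:
            raise ValueError(
                f"jnd_mean_cents must exceed the {JND_FLOOR_CENTS}-cent floor"
            )

    @property
    def label(self) -> str:
        return f"{self.group}-{'singer' if self.singer else 'non-singer'}"


def default_cells() -> list[CellSpec]:
    """The four cells with the published composition and threshold moments."""
    return [
        CellSpec("control", False, n=17, n_male=5,
                 age_mean_yr=39, age_sd_yr=15,
                 jnd_mean_cents=25.5, jnd_sd_cents=15.7),
        CellSpec("control", True, n=43, n_male=5,
                 age_mean_yr=23, age_sd_yr=5,
                 jnd_mean_cents=18.9, jnd_sd_cents=7.5),
        CellSpec("HVD", False, n=17, n_male=5,
                 age_mean_yr=39, age_sd_yr=13,
                 jnd_mean_cents=45.1, jnd_sd_cents=24.4),
        CellSpec("HVD", True, n=43, n_male=5,
                 age_mean_yr=26, age_sd_yr=10,
                 jnd_mean_cents=25.0, jnd_sd_cents=12.8),
    ]


@dataclass
class ParticipantRecord:
    """One synthetic participant and their session outcome."""

    id: str
    group: str
    singer: bool
    sex: str  # "M" | "F"
    age_yr: float
    true_jnd_cents: float
    estimated_threshold_cents: float | None = None
    catch_accuracy: float | None = None


def _gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape and scale of the shifted gamma matching (mean, sd) above the floor."""
    excess = mean - JND_FLOOR_CENTS
    shape = (excess / sd) ** 2
    scale = sd**2 / excess
    return shape, scale


def sample_jnd(cell: CellSpec, rng: np.random.Generator,
               size: int | None = None) -> np.ndarray | float:
    """Draw true JNDs: floor + gamma with the cell's mean and SD."""
    shape, scale = _gamma_moments(cell.jnd_mean_cents, cell.jnd_sd_cents)
    return JND_FLOOR_CENTS + rng.gamma(shape, scale, size=size)


def _sample_age(cell: CellSpec, rng: np.random.Generator) -> float:
    """Normal age, rejection-sampled above the adult floor."""
    for _ in range(1000):
        age = rng.normal(cell.age_mean_yr, cell.age_sd_yr)
        if age >= MIN_AGE_YR:
            return float(age)
    raise RuntimeError("age distribution places almost no mass above 18")


def sample_participant(cell: CellSpec, rng: np.random.Generator,
                       sex: str | None = None, pid: str = "p0") -> ParticipantRecord:
    """Draw one participant (age, sex, true JND) from a cell specification.

    Sex is supplied by the caller when exact per-cell counts are enforced;
    otherwise it is drawn with probability n_male/n.
    """
    if sex is None:
        sex = "M" if rng.random() < cell.n_male / cell.n else "F"
    age = _sample_age(cell, rng)
    jnd = float(sample_jnd(cell, rng))
    jnd += cell.age_slope_cents_per_yr * (age - cell.age_mean_yr)
    jnd = max(jnd, JND_FLOOR_CENTS)
    return ParticipantRecord(id=pid, group=cell.group, singer=cell.singer,
                             sex=sex, age_yr=age, true_jnd_cents=jnd)


def generate_study(
    cells: Sequence[CellSpec] | None = None,
    config: StaircaseConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    lapse_rate: float = 0.02,
    catch_accuracy_targets: dict[str, float] | None = None,
    run_sessions: bool = True,
) -> pd.DataFrame:
    """Simulate a complete study: sample every participant and run sessions.

    For each participant an observer is calibrated so that its 70.7% point
    equals the participant's true JND and its catch accuracy matches the
    group's target; a full adaptive session then yields the estimated
    threshold.  Flagged sessions (too few reversals) are kept in the table
    with a missing threshold — participants are never silently dropped.

    Returns a DataFrame with columns id, group, singer, sex, age_yr,
    true_jnd_cents, estimated_threshold_cents, catch_accuracy.
    """
    cells = list(cells) if cells is not None else default_cells()
    config = config or StaircaseConfig()
    targets = catch_accuracy_targets or CATCH_ACCURACY_TARGETS
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    cell_streams = ss.spawn(len(cells))

    records: list[ParticipantRecord] = []
    for cell, cstream in zip(cells, cell_streams):
        sample_ss, *session_ss = cstream.spawn(cell.n + 1)
        rng = np.random.default_rng(sample_ss)
        sexes = np.array(["M"] * cell.n_male + ["F"] * (cell.n - cell.n_male))
        rng.shuffle(sexes)
        for i, (sex, sess_seed) in enumerate(zip(sexes, session_ss)):
            pid = f"{cell.label}-{i:03d}"
            rec = sample_participant(cell, rng, sex=str(sex), pid=pid)
            if run_sessions:
                observer = calibrate(rec.true_jnd_cents,
                                     targets[cell.group], lapse_rate)
                result = run_session(observer, config, sess_seed)
                rec.estimated_threshold_cents = result.threshold_cents
                rec.catch_accuracy = result.catch_accuracy
            records.append(rec)

    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "singer": [r.singer for r in records],
            "sex": [r.sex for r in records],
            "age_yr": [r.age_yr for r in records],
            "true_jnd_cents": [r.true_jnd_cents for r in records],
            "estimated_threshold_cents": [
                np.nan if r.estimated_threshold_cents is None
                else r.estimated_threshold_cents for r in records
            ],
            "catch_accuracy": [
                np.nan if r.catch_accuracy is None else r.catch_accuracy
                for r in records
            ],
        }
    )
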