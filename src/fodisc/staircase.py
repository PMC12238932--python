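"""Transformed up-down (2-down/1-up) adaptive staircase.

The comparison's fo shift starts at +60 cents and moves in 4-cent steps:
down after two consecutive correct responses, up after one incorrect
response.  This rule converges on the shift where the probability of a
correct response is 2^(-1/2) ≈ 70.7%.  The track terminates after ten
reversals (direction changes of the realized shift adjustments) or 60
adaptive trials, whichever comes first, and the threshold is the mean of
the shift levels at the last four reversals.  Catch trials — the reference
played twice, shift 0 — are interleaved with probability 0.2; they never
touch the staircase state and are scored only for attention (a "same"
response is correct).

Conventions the source procedure leaves open, made explicit here:

* The initial descent is not a reversal; reversal #1 is the first
  direction change after at least one realized adjustment.
* The shift recorded at a reversal is the level presented on the trial
  whose adjustment changed direction (the pre-adjustment level).
* The 60-trial cap counts adaptive trials only; catch trials are extra.
* The shift is floored at one step (4 cents) so every adaptive trial
  contains a physical difference; there is no ceiling.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from fodisc.observer import ObserverParams, respond


class StaircaseError(Exception):
    """Base class for staircase protocol errors."""


class InsufficientReversalsError(StaircaseError):
    """Raised when fewer reversals than required for threshold estimation."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive track and catch-trial interleaving."""

    initial_shift_cents: float = 60.0
    step_cents: float = 4.0
    n_down: int = 2
    n_up: int = 1
    max_reversals: int = 10
    max_adaptive_trials: int = 60
    catch_probability: float = 0.20
    threshold_reversal_count: int = 4
    min_shift_cents: float | None = None  # defaults to step_cents

    def __post_init__(self) -> None:
        if min(self.n_down, self.n_up, self.max_reversals,
               self.max_adaptive_trials, self.threshold_reversal_count) < 1:
            raise ValueError("all staircase counts must be positive")
        if self.step_cents <= 0 or self.initial_shift_cents <= 0:
            raise ValueError("shifts and steps must be positive")
        if not 0 <= self.catch_probability < 1:
            raise ValueError("catch_probability must be in [0, 1)")
        if self.min_shift_cents is None:
            object.__setattr__(self, "min_shift_cents", self.step_cents)
        elif self.min_shift_cents < 0:
            raise ValueError("min_shift_cents must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    """One logged trial of a session."""

    trial_index: int
    is_catch: bool
    shift_cents: float
    response: str  # "same" | "different"
    correct: bool
    reversal: bool

    def __post_init__(self) -> None:
        if self.is_catch and (self.shift_cents != 0.0 or self.reversal):
            raise ValueError("catch trials have shift 0 and no reversal")


@dataclass
class SessionResult:
    """Complete record of one adaptive session.

    ``threshold_cents`` is None when the session is flagged unusable
    (fewer reversals than ``threshold_reversal_count``); ``catch_accuracy``
    is None when no catch trial occurred.
    """

    trials: list[TrialRecord]
    reversal_shifts: list[float]
    threshold_cents: float | None
    catch_accuracy: float | None
    terminated_by: str  # "reversals" | "trials"
    seed: int | None
    config: StaircaseConfig

    @property
    def flagged(self) -> bool:
        return self.threshold_cents is None

    @property
    def n_adaptive_trials(self) -> int:
        return sum(not t.is_catch for t in self.trials)

    @property
    def n_catch_trials(self) -> int:
        return sum(t.is_catch for t in self.trials)


class Staircase:
    """Mutable 2-down/1-up track state.

    Only adaptive trials pass through :meth:`update`; catch trials are
    transparent to the track.
    """

    def __init__(self, config: StaircaseConfig):
        self.config = config
        self.shift_cents: float = config.initial_shift_cents
        self._consecutive_correct = 0
        self._last_direction = 0  # 0 until the first realized adjustment
        self.reversal_shifts: list[float] = []
        self.n_adaptive_trials = 0

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_shifts)

    def is_terminated(self) -> bool:
        """True once the reversal or adaptive-trial bound is reached."""
        return (self.n_reversals >= self.config.max_reversals
                or self.n_adaptive_trials >= self.config.max_adaptive_trials)

    def update(self, correct: bool) -> bool:
        """Register an adaptive-trial response; return the reversal flag.

        Incorrect responses step the shift up immediately; the ``n_down``-th
        consecutive correct response steps it down (not below the floor).
        A reversal is flagged when the realized adjustment's direction
        differs from the previous realized adjustment's.
        """
        if self.is_terminated():
            raise StaircaseError("update() called on a terminated staircase")
        self.n_adaptive_trials += 1
        level = self.shift_cents
        reversal = False
        if correct:
            self._consecutive_correct += 1
            if self._consecutive_correct >= self.config.n_down:
                self._consecutive_correct = 0
                new = max(level - self.config.step_cents,
                          self.config.min_shift_cents)
                if new < level:
                    reversal = self._realize(level, direction=-1)
        else:
            self._consecutive_correct = 0
            self.shift_cents = level + self.config.step_cents
            reversal = self._realize(level, direction=+1, already_moved=True)
        return reversal

    def _realize(self, level: float, direction: int,
                 already_moved: bool = False) -> bool:
        if not already_moved:
            self.shift_cents = level + direction * self.config.step_cents
        reversal = self._last_direction != 0 and direction != self._last_direction
        if reversal:
            self.reversal_shifts.append(level)
        self._last_direction = direction
        return reversal


def estimate_threshold(reversal_shifts: list[float], k: int = 4) -> float:
    """Mean of the last ``k`` reversal shift levels, in cents."""
    if len(reversal_shifts) < k:
        raise InsufficientReversalsError(
            f"need {k} reversals, got {len(reversal_shifts)}"
        )
    return float(np.mean(reversal_shifts[-k:]))


def draw_trial_kind(rng: np.random.Generator, catch_probability: float) -> bool:
    """Bernoulli draw: True → catch trial."""
    return bool(rng.random() < catch_probability)


def catch_accuracy(trials: list[TrialRecord]) -> float | None:
    """Fraction of catch trials answered "same"; None without catch trials."""
    catch = [t for t in trials if t.is_catch]
    if not catch:
        return None
    return sum(t.correct for t in catch) / len(catch)


def run_session(
    observer: ObserverParams,
    config: StaircaseConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> SessionResult:
    """Simulate one full adaptive session for a synthetic observer.

    The random stream is split into independent substreams for trial-kind
    draws and observer responses, so the same seed replays the identical
    session.  Sessions ending with too few reversals are returned flagged
    (``threshold_cents`` None), never raised.
    """
    config = config or StaircaseConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    kind_rng, response_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    stair = Staircase(config)
    trials: list[TrialRecord] = []
    index = 0
    while not stair.is_terminated():
        if draw_trial_kind(kind_rng, config.catch_probability):
            resp = respond(observer, 0.0, response_rng)
            trials.append(TrialRecord(index, True, 0.0, resp,
                                      correct=(resp == "same"), reversal=False))
        else:
            level = stair.shift_cents
            resp = respond(observer, level, response_rng)
            correct = resp == "different"
            reversal = stair.update(correct)
            trials.append(TrialRecord(index, False, level, resp,
                                      correct=correct, reversal=reversal))
        index += 1

    terminated_by = ("reversals"
                     if stair.n_reversals >= config.max_reversals else "trials")
    try:
        threshold = estimate_threshold(stair.reversal_shifts,
                                       config.threshold_reversal_count)
    except InsufficientReversalsError:
        threshold = None
    seed_out = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    return SessionResult(
        trials=trials,
        reversal_shifts=list(stair.reversal_shifts),
        threshold_cents=threshold,
        catch_accuracy=catch_accuracy(trials),
        terminated_by=terminated_by,
        seed=seed_out if isinstance(seed_out, int) else None,
        config=config,
    )


# ---------------------------------------------------------------------------
# session logging

CSV_COLUMNS = ["trial_index", "is_catch", "shift_cents",
               "response", "correct", "reversal"]


def write_session_csv(result: SessionResult, path: str | Path) -> None:
    """One row per trial, in presentation order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for t in result.trials:
            writer.writerow([t.trial_index, int(t.is_catch), t.shift_cents,
                             t.response, int(t.correct), int(t.reversal)])


def read_session_csv(path: str | Path) -> list[TrialRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        TrialRecord(int(r["trial_index"]), bool(int(r["is_catch"])),
                    float(r["shift_cents"]), r["response"],
                    bool(int(r["correct"])), bool(int(r["reversal"])))
        for r in rows
    ]


def session_summary(result: SessionResult) -> dict:
    """JSON-serializable session summary including the config echo."""
    return {
        "threshold_cents": result.threshold_cents,
        "reversal_shifts": result.reversal_shifts,
        "catch_accuracy": result.catch_accuracy,
        "terminated_by": result.terminated_by,
        "flagged": result.flagged,
        "n_adaptive_trials": result.n_adaptive_trials,
        "n_catch_trials": result.n_catch_trials,
        "seed": result.seed,
        "config": asdict(result.config),
    }


def write_session_summary(result: SessionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session_summary(result), indent=2))
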