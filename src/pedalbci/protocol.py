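"""Experimental protocol: timing constants, cue schedules, stimulation dose.

A session consists of ``trials_per_session`` trials. Each trial presents the
two mental tasks -- RELAX and pedaling-IMAGINE -- ``tasks_per_type_per_trial``
times each, in randomized order, with the constraint that the same task never
appears more than twice in a row (so subjects cannot anticipate the next cue).
A fixation cross separates consecutive tasks. The first ``training_trials``
trials feed the classifier; the remainder are evaluated online.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml

RELAX = "RELAX"
IMAGINE = "IMAGINE"
CUE_CROSS = "CUE_CROSS"

TASK_LABELS = (RELAX, IMAGINE)


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and structure of one experimental session.

    Defaults follow the cue protocol of the study this package models:
    5.8 s tasks separated by 3 s fixation crosses, ten tasks of each type
    per trial, ten trials per day, the first four used for training. Online
    analysis uses 1 s epochs shifted by 200 ms, skipping the first two
    seconds of each task (cue-reaction transient).
    """

    task_duration_s: float = 5.8
    inter_cue_duration_s: float = 3.0
    tasks_per_type_per_trial: int = 10
    trials_per_session: int = 10
    training_trials: int = 4
    discard_initial_s: float = 2.0
    epoch_length_s: float = 1.0
    epoch_shift_s: float = 0.2
    sampling_rate_hz: float = 500.0
    n_days: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.task_duration_s, self.inter_cue_duration_s,
               self.epoch_length_s, self.epoch_shift_s,
               self.sampling_rate_hz) <= 0:
            raise ProtocolError("all durations and rates must be positive")
        if self.discard_initial_s < 0:
            raise ProtocolError("discard_initial_s must be non-negative")
        if self.epoch_shift_s > self.epoch_length_s:
            raise ProtocolError("epoch_shift_s must not exceed epoch_length_s")
        if self.discard_initial_s + self.epoch_length_s > self.task_duration_s:
            raise ProtocolError(
                "discard_initial_s + epoch_length_s must fit inside the task")
        if not (0 < self.training_trials < self.trials_per_session):
            raise ProtocolError(
                "training_trials must be in (0, trials_per_session)")
        if self.tasks_per_type_per_trial < 1 or self.n_days < 1:
            raise ProtocolError("counts must be >= 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        return cls.from_dict(json.loads(text))

    # -- derived timing ---------------------------------------------------

    @property
    def trial_duration_s(self) -> float:
        """One trial: a cross precedes every task, including the first."""
        n_tasks = 2 * self.tasks_per_type_per_trial
        return n_tasks * (self.inter_cue_duration_s + self.task_duration_s)

    @property
    def session_duration_s(self) -> float:
        return self.trials_per_session * self.trial_duration_s


@dataclass(frozen=True)
class ScheduleEvent:
    """A single cue interval: task label, onset and duration in seconds."""

    label: str
    onset_s: float
    duration_s: float
    trial: int = 0  # 1-based trial index

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def _balanced_order_no_triples(n_per_type: int, rng: np.random.Generator) -> list[str]:
    """Random balanced RELAX/IMAGINE order with max run length 2.

    Rejection sampling over balanced permutations: uniform over the
    admissible orders, and cheap (for n=10 roughly 1 in 6 shuffles passes).
    """
    labels = np.array([0] * n_per_type + [1] * n_per_type)
    while True:
        rng.shuffle(labels)
        run, ok = 1, True
        for a, b in zip(labels[:-1], labels[1:]):
            run = run + 1 if a == b else 1
            if run > 2:
                ok = False
                break
        if ok:
            return [TASK_LABELS[i] for i in labels]


def build_trial_schedule(
    spec: ProtocolSpec,
    seed: int,
    *,
    start_s: float = 0.0,
    trial: int = 1,
) -> list[ScheduleEvent]:
    """Randomized cue schedule for one trial.

    Returns an ordered, non-overlapping list of events: a fixation cross
    before every task, then ``tasks_per_type_per_trial`` RELAX and as many
    IMAGINE events of ``task_duration_s`` each. Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    order = _balanced_order_no_triples(spec.tasks_per_type_per_trial, rng)
    events: list[ScheduleEvent] = []
    t = start_s
    for label in order:
        events.append(ScheduleEvent(CUE_CROSS, t, spec.inter_cue_duration_s, trial))
        t += spec.inter_cue_duration_s
        events.append(ScheduleEvent(label, t, spec.task_duration_s, trial))
        t += spec.task_duration_s
    return events


def build_session_schedule(spec: ProtocolSpec, seed: int) -> list[ScheduleEvent]:
    """Concatenated schedules of all trials in a session.

    Trial k uses a child seed spawned from ``seed`` so trials are mutually
    independent but the whole session is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    events: list[ScheduleEvent] = []
    t = 0.0
    for k, child in enumerate(ss.spawn(spec.trials_per_session), start=1):
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        events.extend(build_trial_schedule(spec, trial_seed, start_s=t, trial=k))
        t += spec.trial_duration_s
    return events


def task_events(events: Iterable[ScheduleEvent]) -> list[ScheduleEvent]:
    """Only the RELAX/IMAGINE events, in order."""
    return [e for e in events if e.label in TASK_LABELS]


def current_density(intensity_mA: float, electrode_radius_cm: float) -> float:
    """Current density (mA/cm^2) of a circular stimulation electrode.

    ``intensity / (pi * r^2)``: 0.4 mA through a 1 cm-radius electrode gives
    0.127 mA/cm^2.
    """
    if intensity_mA <= 0 or electrode_radius_cm <= 0:
        raise ValueError("intensity and radius must be positive")
    return intensity_mA / (math.pi * electrode_radius_cm**2)


def epochs_per_task(spec: ProtocolSpec) -> int:
    """Number of sliding-epoch start positions within one task interval.

    Epoch starts at ``discard_initial_s + k * epoch_shift_s`` for k = 0, 1,
    ... while the 1 s window still fits inside the task; a 1e-9 s tolerance
    keeps exactly-fitting end windows (5.8 - 1.0 = 4.8 is reachable from 2.0
    in 0.2 s steps only up to floating point).
    """
    spec.validate()
    usable = spec.task_duration_s - spec.discard_initial_s - spec.epoch_length_s
    return int(math.floor(usable / spec.epoch_shift_s + 1e-9)) + 1


def epoch_start_times(spec: ProtocolSpec, event_onset_s: float = 0.0) -> np.ndarray:
    """Epoch start times (s) for a task event beginning at ``event_onset_s``."""
    n = epochs_per_task(spec)
    return event_onset_s + spec.discard_initial_s + spec.epoch_shift_s * np.arange(n)


def schedule_to_table(events: Iterable[ScheduleEvent]) -> str:
    """3-column delimited export (label, onset_s, duration_s), tab separated."""
    lines = ["label\tonset_s\tduration_s"]
    for e in events:
        lines.append(f"{e.label}\t{e.onset_s:.3f}\t{e.duration_s:.3f}")
    return "\n".join(lines) + "\n"


def schedule_from_table(text: str) -> list[ScheduleEvent]:
    events = []
    for line in text.strip().splitlines()[1:]:
        label, onset, dur = line.split("\t")
        events.append(ScheduleEvent(label, float(onset), float(dur)))
    return events
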