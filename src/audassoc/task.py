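"""Two-task, two-tone go/no-go paradigm: labels, outcomes, and d-prime.

Each trial presents a sequence of two 200-ms tones (S1, S2) separated by an
800-ms silent delay; every tone is either 1 kHz or 3 kHz, giving the four
sequences 3-3, 3-1, 1-3 and 1-1.  In Task 1 the subject must release a touch
bar within a response window after S2 (a *go* response) when the sequence is
3-3 and withhold the release (*no-go*) otherwise; in Task 2 the go sequence
is 1-1.  Because the same physical tone demands different responses in the
two tasks, every tone presentation carries one of five sensorimotor
association labels from the viewpoint of an ideal observer:

* ``S1_NO_GO`` -- S1 alone already determines that no-go is required
  (S1 is not the first tone of the task's go sequence);
* ``S1_UNCERTAIN`` -- S1 matches the go sequence's first tone, so the
  required response is still open;
* ``S2_GO`` / ``S2_NO_GO`` -- after an uncertain S1, S2 resolves the trial
  to go or no-go;
* ``S2_NIL`` -- S1 already settled the trial, so S2 carries no response
  information.

This module encodes the task rules, labels tone presentations, classifies
behavioral outcomes against the response window, and computes the
signal-detection discriminability d' per no-go sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from scipy.stats import norm

from .errors import InvalidInputError

__all__ = [
    "Task",
    "Position",
    "Condition",
    "Response",
    "Outcome",
    "TaskSpec",
    "ToneSequence",
    "TrialOutcome",
    "LOW_FREQ",
    "HIGH_FREQ",
    "TONE_FREQS",
    "RESPONSE_WINDOW_MONKEY_L",
    "RESPONSE_WINDOW_MONKEY_C",
    "required_response",
    "label_condition",
    "label_sequence",
    "classify_outcome",
    "dprime",
    "behavioral_summary",
]

LOW_FREQ = 1000.0
HIGH_FREQ = 3000.0
TONE_FREQS = (LOW_FREQ, HIGH_FREQ)

#: Response window (s after S2 offset), half-open [start, end).
RESPONSE_WINDOW_MONKEY_L = (0.040, 1.160)
RESPONSE_WINDOW_MONKEY_C = (0.040, 1.760)


class Task(str, Enum):
    TASK1 = "TASK1"
    TASK2 = "TASK2"


class Position(str, Enum):
    S1 = "S1"
    S2 = "S2"


class Condition(str, Enum):
    S1_NO_GO = "S1_NO_GO"
    S1_UNCERTAIN = "S1_UNCERTAIN"
    S2_GO = "S2_GO"
    S2_NO_GO = "S2_NO_GO"
    S2_NIL = "S2_NIL"


class Response(str, Enum):
    GO = "GO"
    NO_GO = "NO_GO"


class Outcome(str, Enum):
    HIT = "HIT"
    MISS = "MISS"
    CORRECT_REJECTION = "CORRECT_REJECTION"
    FALSE_ALARM = "FALSE_ALARM"


#: Frequency whose repetition forms the go sequence in each task.
GO_FREQUENCY = {Task.TASK1: HIGH_FREQ, Task.TASK2: LOW_FREQ}


def _check_freq(freq: float) -> float:
    freq = float(freq)
    if freq not in TONE_FREQS:
        raise InvalidInputError(
            f"tone frequency must be one of {TONE_FREQS} Hz, got {freq!r}"
        )
    return freq


@dataclass(frozen=True)
class TaskSpec:
    """One of the two task rules (go sequence, cue, response window)."""

    task: Task
    response_window: tuple[float, float] = RESPONSE_WINDOW_MONKEY_L
    cue: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        t_min, t_max = self.response_window
        if not (0.0 < t_min < t_max):
            raise InvalidInputError(
                f"response window must satisfy 0 < t_min < t_max, got {self.response_window}"
            )
        if not self.cue:
            object.__setattr__(
                self,
                "cue",
                "green LED, right" if self.task is Task.TASK1 else "red LED, left",
            )

    @property
    def go_frequency(self) -> float:
        return GO_FREQUENCY[self.task]

    @property
    def other_frequency(self) -> float:
        return HIGH_FREQ if self.go_frequency == LOW_FREQ else LOW_FREQ

    @property
    def go_sequence(self) -> tuple[float, float]:
        """The (S1, S2) frequency pair that requires the go response."""
        return (self.go_frequency, self.go_frequency)


@dataclass(frozen=True)
class ToneSequence:
    """Timing and frequencies of the two-tone sequence within a trial.

    ``s1_onset`` is measured on the trial's own clock (the per-trial anchor
    supplied by the events table); the 1.0-s stimulus-onset interval yields
    the 800-ms silent delay between S1 offset and S2 onset.
    """

    s1_freq: float
    s2_freq: float
    s1_onset: float = 0.0
    tone_duration: float = 0.200
    onset_interval: float = 1.000

    def __post_init__(self) -> None:
        _check_freq(self.s1_freq)
        _check_freq(self.s2_freq)
        if self.tone_duration <= 0 or self.onset_interval <= 0:
            raise InvalidInputError("timing fields must be positive")
        if self.onset_interval <= self.tone_duration:
            raise InvalidInputError(
                "onset interval must exceed the tone duration (tones may not overlap)"
            )

    @property
    def s1_offset(self) -> float:
        return self.s1_onset + self.tone_duration

    @property
    def s2_onset(self) -> float:
        return self.s1_onset + self.onset_interval

    @property
    def s2_offset(self) -> float:
        return self.s2_onset + self.tone_duration

    @property
    def delay(self) -> float:
        """Silent gap between S1 offset and S2 onset (s)."""
        return self.onset_interval - self.tone_duration

    @property
    def frequencies(self) -> tuple[float, float]:
        return (self.s1_freq, self.s2_freq)


@dataclass(frozen=True)
class TrialOutcome:
    """Behavioral outcome of one trial, with the release time if any."""

    outcome: Outcome
    release_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", Outcome(self.outcome))


def required_response(spec: TaskSpec, seq: ToneSequence) -> Response:
    """Return the response the task rules require for ``seq``.

    GO if and only if the sequence's frequency pair equals the task's go
    sequence (both tones at the task's go frequency).
    """
    return Response.GO if seq.frequencies == spec.go_sequence else Response.NO_GO


def label_condition(
    spec: TaskSpec | Task,
    position: Position | str,
    tone_freq: float,
    s1_freq: float | None = None,
) -> Condition:
    """Sensorimotor-association label of a single tone presentation.

    For an S2 label the frequency of the preceding S1 must be supplied,
    because S2's meaning depends on whether S1 already resolved the trial.
    """
    if not isinstance(spec, TaskSpec):
        spec = TaskSpec(Task(spec))
    position = Position(position)
    tone_freq = _check_freq(tone_freq)
    go = spec.go_frequency
    if position is Position.S1:
        return Condition.S1_UNCERTAIN if tone_freq == go else Condition.S1_NO_GO
    if s1_freq is None:
        raise InvalidInputError("labeling an S2 requires the S1 frequency")
    s1_freq = _check_freq(s1_freq)
    if s1_freq != go:
        # S1 already signaled no-go; S2 carries no response information.
        return Condition.S2_NIL
    return Condition.S2_GO if tone_freq == go else Condition.S2_NO_GO


def label_sequence(spec: TaskSpec, seq: ToneSequence) -> tuple[Condition, Condition]:
    """Labels of (S1, S2) for a full sequence under a task."""
    return (
        label_condition(spec, Position.S1, seq.s1_freq),
        label_condition(spec, Position.S2, seq.s2_freq, s1_freq=seq.s1_freq),
    )


def classify_outcome(
    required: Response,
    release_time: float | None,
    window: tuple[float, float],
) -> TrialOutcome:
    """Classify a trial outcome from the (possibly absent) bar release.

    ``window`` is the absolute response window on the trial clock, half-open
    [start, end).  An absent release is a valid state (MISS or CORRECT
    REJECTION depending on the required response).
    """
    required = Response(required)
    t0, t1 = window
    released = (
        release_time is not None
        and not (isinstance(release_time, float) and math.isnan(release_time))
        and t0 <= release_time < t1
    )
    if required is Response.GO:
        outcome = Outcome.HIT if released else Outcome.MISS
    else:
        outcome = Outcome.FALSE_ALARM if released else Outcome.CORRECT_REJECTION
    return TrialOutcome(outcome, release_time)


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Signal-detection d' = z(hit) - z(fa) with a 1/(2n) extreme-rate correction.

    Rates of exactly 0 or 1 are replaced by 1/(2n) and 1 - 1/(2n)
    respectively (n being the trial count on that side) so that the normal
    quantile stays finite.
    """
    n_go, n_nogo = int(n_go), int(n_nogo)
    if n_go < 1 or n_nogo < 1:
        raise InvalidInputError("trial counts must be >= 1")
    for name, rate in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= rate <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {rate!r}")

    def corrected(rate: float, n: int) -> float:
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    return float(
        norm.ppf(corrected(hit_rate, n_go)) - norm.ppf(corrected(fa_rate, n_nogo))
    )


def behavioral_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Per-task hit rate, and false-alarm rate + d' per no-go sequence.

    ``events`` must carry columns ``task``, ``s1_freq``, ``s2_freq``,
    ``required`` and ``outcome`` (strings as produced by the session
    generator / bundle reader).  Returns one row per (task, no-go sequence).
    """
    if events.empty:
        raise InvalidInputError("empty events table")
    rows = []
    for task, df in events.groupby("task", sort=True):
        go = df[df["required"] == Response.GO.value]
        nogo = df[df["required"] == Response.NO_GO.value]
        if len(go) == 0 or len(nogo) == 0:
            continue
        hit_rate = float((go["outcome"] == Outcome.HIT.value).mean())
        for (f1, f2), seq_df in nogo.groupby(["s1_freq", "s2_freq"], sort=True):
            fa_rate = float((seq_df["outcome"] == Outcome.FALSE_ALARM.value).mean())
            rows.append(
                {
                    "task": task,
                    "s1_freq": f1,
                    "s2_freq": f2,
                    "n_go": len(go),
                    "n_nogo": len(seq_df),
                    "hit_rate": hit_rate,
                    "fa_rate": fa_rate,
                    "dprime": dprime(hit_rate, fa_rate, len(go), len(seq_df)),
                }
            )
    if not rows:
        raise InvalidInputError("events table contains no complete task data")
    return pd.DataFrame(rows)
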