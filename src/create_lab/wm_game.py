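"""Adaptive sequence-recall task engine and session scoring.

The engine runs a trial loop in which a sequence is shown for a display
duration, the (simulated) player reproduces it, and difficulty is
re-evaluated every ``eval_window`` trials: sustained accuracy above
``up_threshold`` raises the level and shortens the display duration,
accuracy below ``down_threshold`` lengthens the duration.  The level only
ever increases; easing works through display time.

Per-trial "score" is the running cumulative accuracy (cumulative correct /
cumulative attempts after that trial).  A partial-credit per-trial mode is
available via ``score_session(..., mode="per_trial")`` for logs that carry
an explicit ``trial_score``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from math import exp
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "GameConfig",
    "GameState",
    "TrialRecord",
    "WMScores",
    "AgentModel",
    "update_difficulty",
    "score_session",
    "simulate_session",
]

_BASE_TIME = datetime(2025, 1, 1, 9, 0, 0)


@dataclass(frozen=True)
class GameConfig:
    eval_window: int = 10
    up_threshold: float = 0.7
    down_threshold: float = 0.3
    initial_duration_ms: int = 1000
    duration_step_ms: int = 100
    min_duration_ms: int = 200
    max_duration_ms: int = 2000
    initial_level: int = 1
    #: level -> sequence length; by default difficulty acts through display
    #: time only and the sequence stays at 9 positions.
    sequence_length_rule: Callable[[int], int] = field(default=lambda level: 9)

    def __post_init__(self) -> None:
        if not self.down_threshold < self.up_threshold:
            raise ValidationError("down_threshold must be < up_threshold")
        if not (self.min_duration_ms <= self.initial_duration_ms <= self.max_duration_ms):
            raise ValidationError("duration schedule must satisfy min <= initial <= max")
        if self.eval_window < 1:
            raise ValidationError("eval_window must be >= 1")


@dataclass(frozen=True)
class GameState:
    level: int
    duration_ms: int


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    level: int
    display_duration_ms: int
    correct: bool
    running_score: float
    timestamp: str
    trial_score: float | None = None  # optional partial credit


@dataclass(frozen=True)
class WMScores:
    num_correct_responses: int
    num_total_responses: int
    max_score: float
    median_score: float
    mean_score: float
    count_above_0_25: int
    count_above_0_5: int
    successive_correct_count: int

    def as_dict(self) -> dict[str, float]:
        return {
            "num_correct_responses": self.num_correct_responses,
            "num_total_responses": self.num_total_responses,
            "max_score": self.max_score,
            "median_score": self.median_score,
            "mean_score": self.mean_score,
            "count_above_0_25": self.count_above_0_25,
            "count_above_0_5": self.count_above_0_5,
            "successive_correct_count": self.successive_correct_count,
        }


@dataclass(frozen=True)
class AgentModel:
    """Synthetic player with a logistic span psychometric function."""

    capacity: float  # sequence length at which recall probability is 0.5
    slope: float = 1.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("slope must be > 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValidationError("lapse must be in [0,1]")

    def recall_probability(self, sequence_length: int) -> float:
        arg = (sequence_length - self.capacity) / self.slope
        if arg > 700.0:  # avoid overflow in exp for extreme capacities
            core = 0.0
        elif arg < -700.0:
            core = 1.0
        else:
            core = 1.0 / (1.0 + exp(arg))
        return self.lapse / 2.0 + (1.0 - self.lapse) * core


def update_difficulty(state: GameState, window_accuracy: float, config: GameConfig) -> GameState:
    """Apply one difficulty evaluation to (level, display duration)."""
    if not 0.0 <= window_accuracy <= 1.0:
        raise ValidationError(f"window accuracy outside [0,1]: {window_accuracy}")
    if window_accuracy > config.up_threshold:
        return GameState(
            level=state.level + 1,
            duration_ms=max(config.min_duration_ms, state.duration_ms - config.duration_step_ms),
        )
    if window_accuracy < config.down_threshold:
        return GameState(
            level=state.level,
            duration_ms=min(config.max_duration_ms, state.duration_ms + config.duration_step_ms),
        )
    return state


def _per_trial_scores(log: Sequence[TrialRecord], mode: str) -> list[float]:
    if mode == "cumulative":
        scores = []
        cum = 0
        for t, rec in enumerate(log, start=1):
            cum += int(rec.correct)
            scores.append(cum / t)
        return scores
    if mode == "per_trial":
        return [rec.trial_score if rec.trial_score is not None else float(rec.correct) for rec in log]
    raise ValidationError(f"unknown score mode: {mode!r}")


def score_session(log: Sequence[TrialRecord], mode: str = "cumulative") -> WMScores:
    """Compute the eight session metrics from an ordered trial log.

    Depends only on the ``correct`` sequence (and ``trial_score`` in
    per-trial mode); timestamps, levels and durations are ignored.
    Count thresholds use strict ``>``.
    """
    log = list(log)
    if not log:
        raise ValidationError("cannot score an empty trial log")
    scores = _per_trial_scores(log, mode)
    n_correct = sum(int(rec.correct) for rec in log)
    streak = best = 0
    for rec in log:
        best = best + 1 if rec.correct else 0
        streak = max(streak, best)
    return WMScores(
        num_correct_responses=n_correct,
        num_total_responses=len(log),
        max_score=max(scores),
        median_score=statistics.median(scores),
        mean_score=sum(scores) / len(scores),
        count_above_0_25=sum(s > 0.25 for s in scores),
        count_above_0_5=sum(s > 0.5 for s in scores),
        successive_correct_count=streak,
    )


def simulate_session(
    agent: AgentModel,
    config: GameConfig,
    n_trials: int,
    seed: int | np.random.Generator,
) -> list[TrialRecord]:
    """Play ``n_trials`` trials of the adaptive loop with a synthetic agent.

    Correctness on each trial is Bernoulli with probability given by the
    agent's psychometric function at the current sequence length; the
    difficulty schedule is re-evaluated every ``eval_window`` trials over
    the accuracy of that window.  Deterministic under seed.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = GameState(level=config.initial_level, duration_ms=config.initial_duration_ms)
    log: list[TrialRecord] = []
    window: list[bool] = []
    cum_correct = 0
    for t in range(1, n_trials + 1):
        seq_len = config.sequence_length_rule(state.level)
        p = agent.recall_probability(seq_len)
        correct = bool(rng.random() < p)
        cum_correct += int(correct)
        window.append(correct)
        log.append(
            TrialRecord(
                trial_index=t,
                level=state.level,
                display_duration_ms=state.duration_ms,
                correct=correct,
                running_score=cum_correct / t,
                timestamp=(_BASE_TIME + timedelta(seconds=3 * t)).isoformat(),
            )
        )
        if t % config.eval_window == 0:
            accuracy = sum(window) / len(window)
            state = update_difficulty(state, accuracy, config)
            window = []
    return log
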