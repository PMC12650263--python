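"""Blink detection from eye-opening-ratio time series and sEBR summaries.

The module boundary is the sampled eye-opening ratio (the waveform a
landmark tracker would produce); no camera or face-tracking dependency.
Detection is a threshold state machine with hysteresis: an event opens
when the ratio drops below ``threshold`` and closes when it rises back
above ``threshold + hysteresis``.  Events shorter than
``min_closed_frames`` are discarded and onsets within ``refractory_ms``
of the previous onset are merged into one blink.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "BlinkConfig",
    "BlinkSession",
    "SEBRSummary",
    "detect_blinks",
    "summarize_sebr",
    "write_session_csv",
]


@dataclass(frozen=True)
class BlinkConfig:
    threshold: float = 0.5
    min_closed_frames: int = 2  # ~66 ms at 30 fps
    refractory_ms: float = 100.0
    hysteresis: float = 0.02

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.min_closed_frames < 1:
            raise ValidationError("min_closed_frames must be >= 1")
        if self.refractory_ms < 0:
            raise ValidationError("refractory_ms must be >= 0")
        if self.hysteresis < 0:
            raise ValidationError("hysteresis must be >= 0")


@dataclass(frozen=True)
class BlinkSession:
    signal: np.ndarray
    fps: float
    events: tuple[tuple[int, int], ...]  # (onset frame, offset frame), half-open
    blink_count: int
    duration_s: float
    metadata: dict = field(default_factory=dict)

    @property
    def blinks_per_minute(self) -> float:
        return 60.0 * self.blink_count / self.duration_s if self.duration_s > 0 else 0.0


@dataclass(frozen=True)
class SEBRSummary:
    sebr_pre: int
    sebr_post: int

    @property
    def sebr_diff(self) -> int:
        return self.sebr_post - self.sebr_pre

    def as_dict(self) -> dict[str, int]:
        return {
            "sebr_pre": self.sebr_pre,
            "sebr_post": self.sebr_post,
            "sebr_diff": self.sebr_diff,
        }


def detect_blinks(
    signal: Sequence[float] | np.ndarray,
    fps: float,
    config: BlinkConfig | None = None,
    metadata: dict | None = None,
) -> BlinkSession:
    """Run the threshold/hysteresis state machine over one recording."""
    config = config or BlinkConfig()
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 1 or sig.size < 2:
        raise ValidationError("signal must be a 1-D series of at least 2 frames")
    if fps <= 0:
        raise ValidationError("fps must be > 0")
    bad = np.flatnonzero(~np.isfinite(sig))
    if bad.size:
        raise ValidationError(f"non-finite sample at frame {int(bad[0])}")

    reopen = config.threshold + config.hysteresis
    raw: list[tuple[int, int]] = []
    onset: int | None = None
    for i, v in enumerate(sig):
        if onset is None:
            if v < config.threshold:
                onset = i
        elif v > reopen:
            raw.append((onset, i))
            onset = None
    if onset is not None:
        raw.append((onset, len(sig)))

    # duration filter, then refractory merge on the survivors
    kept = [(a, b) for a, b in raw if b - a >= config.min_closed_frames]
    refractory_frames = config.refractory_ms * fps / 1000.0
    events: list[tuple[int, int]] = []
    for a, b in kept:
        if events and (a - events[-1][0]) < refractory_frames:
            events[-1] = (events[-1][0], b)
        else:
            events.append((a, b))

    return BlinkSession(
        signal=sig,
        fps=float(fps),
        events=tuple(events),
        blink_count=len(events),
        duration_s=sig.size / fps,
        metadata=dict(metadata or {}),
    )


def summarize_sebr(pre: BlinkSession, post: BlinkSession) -> SEBRSummary:
    """Pre/post blink counts and their signed difference (post - pre)."""
    return SEBRSummary(sebr_pre=pre.blink_count, sebr_post=post.blink_count)


def write_session_csv(session: BlinkSession, path, config: BlinkConfig | None = None) -> None:
    """Persist the session record (one summary row, optional event rows)."""
    config = config or BlinkConfig()
    meta = session.metadata
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "age", "sex", "threshold", "duration_s", "blink_count"])
        writer.writerow(
            [
                meta.get("name", ""),
                meta.get("age", ""),
                meta.get("sex", ""),
                config.threshold,
                f"{session.duration_s:.3f}",
                session.blink_count,
            ]
        )
        writer.writerow([])
        writer.writerow(["event_index", "onset_frame", "offset_frame", "onset_s"])
        for idx, (a, b) in enumerate(session.events, start=1):
            writer.writerow([idx, a, b, f"{a / session.fps:.3f}"])
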