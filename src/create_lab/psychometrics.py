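"""Sleep-quality (PSQI) and emotion-regulation (ERQ) instrument scoring.

PSQI: 19 self-rated items reduce to seven components, each scored 0-3, and
a global score of 0-21 (higher = worse sleep).  Scoring follows the
published instrument rules: latency/duration/efficiency banding,
disturbance-sum banding, and component summation.  The good/poor sleeper
split uses a global threshold of 5 with ``global > threshold`` classified
Poor, consistent with higher-is-worse scoring.

ERQ: 10 items on a 1-7 Likert scale; Cognitive Reappraisal sums the six
standard reappraisal items (1, 3, 5, 7, 8, 10) and Expressive Suppression
the remaining four (2, 4, 6, 9).  The item map is module-level data and
can be overridden per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "PSQI_ITEM_IDS",
    "ERQ_REAPPRAISAL_ITEMS",
    "ERQ_SUPPRESSION_ITEMS",
    "PSQIScores",
    "ERQScores",
    "score_psqi",
    "score_erq",
    "classify_sleeper",
]

#: The 19 self-rated items expected by :func:`score_psqi`.
PSQI_ITEM_IDS = (
    "q1_bedtime",          # clock time HH:MM
    "q2_latency_min",      # minutes to fall asleep
    "q3_waketime",         # clock time HH:MM
    "q4_sleep_hours",      # actual sleep per night (hours)
    "q5a", "q5b", "q5c", "q5d", "q5e", "q5f", "q5g", "q5h", "q5i", "q5j",  # 0-3
    "q5j_desc",            # free text, unscored
    "q6_quality",          # 0-3
    "q7_medication",       # 0-3
    "q8_sleepy",           # 0-3
    "q9_enthusiasm",       # 0-3
)

_PSQI_ORDINAL_ITEMS = (
    "q5a", "q5b", "q5c", "q5d", "q5e", "q5f", "q5g", "q5h", "q5i", "q5j",
    "q6_quality", "q7_medication", "q8_sleepy", "q9_enthusiasm",
)

ERQ_REAPPRAISAL_ITEMS = (1, 3, 5, 7, 8, 10)
ERQ_SUPPRESSION_ITEMS = (2, 4, 6, 9)

PSQI_COMPONENT_NAMES = (
    "subjective_quality",
    "latency",
    "duration",
    "efficiency",
    "disturbances",
    "medication",
    "daytime_dysfunction",
)


@dataclass(frozen=True)
class PSQIScores:
    subjective_quality: int
    latency: int
    duration: int
    efficiency: int
    disturbances: int
    medication: int
    daytime_dysfunction: int
    global_score: int
    group: str  # "Good" | "Poor"

    @property
    def components(self) -> tuple[int, ...]:
        return (
            self.subjective_quality,
            self.latency,
            self.duration,
            self.efficiency,
            self.disturbances,
            self.medication,
            self.daytime_dysfunction,
        )

    def as_dict(self) -> dict[str, object]:
        d = {f"psqi_{name}": comp for name, comp in zip(PSQI_COMPONENT_NAMES, self.components)}
        d["psqi_global"] = self.global_score
        d["sleep_group"] = self.group
        return d


@dataclass(frozen=True)
class ERQScores:
    cognitive_reappraisal: int
    expressive_suppression: int
    total: int

    def as_dict(self) -> dict[str, int]:
        return {
            "er_reappraisal": self.cognitive_reappraisal,
            "er_suppression": self.expressive_suppression,
            "er_total": self.total,
        }


def _parse_clock(value: object, item: str) -> datetime:
    try:
        return datetime.strptime(str(value).strip(), "%H:%M")
    except ValueError as err:
        raise ValidationError(f"unparseable clock time for {item}: {value!r}") from err


def _ordinal(value: object, item: str, lo: int = 0, hi: int = 3) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"non-integer response for {item}: {value!r}") from err
    if not lo <= v <= hi:
        raise ValidationError(f"response for {item} outside [{lo},{hi}]: {v}")
    return v


def _band(value: float, cuts: Sequence[float]) -> int:
    """Score 0..3 by how many ascending cut points the value exceeds."""
    score = 0
    for cut in cuts:
        if value > cut:
            score += 1
    return score


def classify_sleeper(global_score: int, threshold: int = 5) -> str:
    """Good/Poor split: global above the threshold means Poor sleep."""
    if not 0 <= global_score <= 21:
        raise ValidationError(f"global score outside [0,21]: {global_score}")
    return "Poor" if global_score > threshold else "Good"


def score_psqi(item_responses: Mapping[str, object], threshold: int = 5) -> PSQIScores:
    """Score the seven components and global from 19 item responses."""
    missing = [item for item in PSQI_ITEM_IDS if item not in item_responses]
    if missing:
        raise ValidationError(f"missing PSQI items: {missing}")
    ord_vals = {item: _ordinal(item_responses[item], item) for item in _PSQI_ORDINAL_ITEMS}

    # C1 subjective quality
    c1 = ord_vals["q6_quality"]

    # C2 latency: banded minutes + q5a, re-banded
    latency_min = float(item_responses["q2_latency_min"])
    if latency_min < 0:
        raise ValidationError(f"negative sleep latency: {latency_min}")
    lat_sum = _band(latency_min, (15, 30, 60)) + ord_vals["q5a"]
    c2 = (0, 1, 1, 2, 2, 3, 3)[lat_sum]

    # C3 duration
    hours = float(item_responses["q4_sleep_hours"])
    if hours < 0:
        raise ValidationError(f"negative sleep hours: {hours}")
    if hours > 7:
        c3 = 0
    elif hours >= 6:
        c3 = 1
    elif hours >= 5:
        c3 = 2
    else:
        c3 = 3

    # C4 habitual efficiency: sleep hours / time in bed
    bed = _parse_clock(item_responses["q1_bedtime"], "q1_bedtime")
    wake = _parse_clock(item_responses["q3_waketime"], "q3_waketime")
    in_bed_h = ((wake - bed).total_seconds() / 3600.0) % 24.0
    if in_bed_h == 0:
        in_bed_h = 24.0
    efficiency = 100.0 * hours / in_bed_h
    if efficiency > 100.0:
        warnings.warn(
            f"sleep efficiency {efficiency:.1f}% exceeds 100%; clamping", stacklevel=2
        )
        efficiency = 100.0
    if efficiency >= 85:
        c4 = 0
    elif efficiency >= 75:
        c4 = 1
    elif efficiency >= 65:
        c4 = 2
    else:
        c4 = 3

    # C5 disturbances: sum of q5b..q5j, banded
    dist_sum = sum(ord_vals[f"q5{ch}"] for ch in "bcdefghij")
    c5 = 0 if dist_sum == 0 else _band(dist_sum, (0, 9, 18))

    # C6 medication
    c6 = ord_vals["q7_medication"]

    # C7 daytime dysfunction
    day_sum = ord_vals["q8_sleepy"] + ord_vals["q9_enthusiasm"]
    c7 = (0, 1, 1, 2, 2, 3, 3)[day_sum]

    global_score = c1 + c2 + c3 + c4 + c5 + c6 + c7
    return PSQIScores(
        subjective_quality=c1,
        latency=c2,
        duration=c3,
        efficiency=c4,
        disturbances=c5,
        medication=c6,
        daytime_dysfunction=c7,
        global_score=global_score,
        group=classify_sleeper(global_score, threshold),
    )


def score_erq(
    item_responses: Mapping[str, object] | Sequence[object],
    reappraisal_items: Sequence[int] = ERQ_REAPPRAISAL_ITEMS,
    suppression_items: Sequence[int] = ERQ_SUPPRESSION_ITEMS,
) -> ERQScores:
    """Score the two subscales from 10 item responses.

    Accepts either a mapping keyed by ``item1``..``item10`` (or bare ints)
    or an ordered 10-element sequence.
    """
    if isinstance(item_responses, Mapping):
        values: dict[int, object] = {}
        for key, val in item_responses.items():
            num = int(str(key).lower().removeprefix("item").removeprefix("q"))
            values[num] = val
    else:
        seq = list(item_responses)
        if len(seq) != 10:
            raise ValidationError(f"ERQ expects 10 items, got {len(seq)}")
        values = {i + 1: v for i, v in enumerate(seq)}
    missing = [i for i in range(1, 11) if i not in values]
    if missing:
        raise ValidationError(f"missing ERQ items: {missing}")
    scored = {i: _ordinal(values[i], f"item{i}", lo=1, hi=7) for i in range(1, 11)}
    reappraisal = sum(scored[i] for i in reappraisal_items)
    suppression = sum(scored[i] for i in suppression_items)
    return ERQScores(
        cognitive_reappraisal=reappraisal,
        expressive_suppression=suppression,
        total=reappraisal + suppression,
    )
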