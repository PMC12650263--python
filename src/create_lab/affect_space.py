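"""Valence-arousal plane analysis of 1-10 stimulus ratings.

Stimulus-level mean valence/arousal place each stimulus in one of four
quadrants (high/low valence x high/low arousal, midpoint 5.5, boundary
counts as low).  The HVHA-deviation predictor is, per participant, the
mean signed difference between their arousal ratings and the stimulus
group-mean arousal over HVHA stimuli only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "QUADRANTS",
    "RatingRecord",
    "classify_quadrant",
    "participant_means",
    "stimulus_means",
    "hvha_deviation",
]

QUADRANTS = ("HVHA", "LVHA", "LVLA", "HVLA")
DEFAULT_MIDPOINT = 5.5


@dataclass(frozen=True)
class RatingRecord:
    participant_id: str
    stimulus_id: str
    arousal: int
    valence: int
    familiarity: int
    comment: str = ""
    timestamp: str = ""
    presentation_index: int | None = None

    def __post_init__(self) -> None:
        for name in ("arousal", "valence", "familiarity"):
            v = getattr(self, name)
            if not 1 <= int(v) <= 10:
                raise ValidationError(f"{name} outside 1-10: {v}")


def classify_quadrant(
    valence_mean: float, arousal_mean: float, midpoint: float = DEFAULT_MIDPOINT
) -> str:
    """Quadrant label; strict ``>`` means values on the midpoint are low."""
    if not (1 <= valence_mean <= 10 and 1 <= arousal_mean <= 10):
        raise ValidationError("means must lie within the 1-10 rating range")
    high_v = valence_mean > midpoint
    high_a = arousal_mean > midpoint
    if high_v:
        return "HVHA" if high_a else "HVLA"
    return "LVHA" if high_a else "LVLA"


def _as_frame(ratings) -> pd.DataFrame:
    if isinstance(ratings, pd.DataFrame):
        df = ratings
    else:
        df = pd.DataFrame([r.__dict__ for r in ratings])
    required = {"participant_id", "stimulus_id", "arousal", "valence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ratings missing columns: {sorted(missing)}")
    return df


def participant_means(ratings) -> pd.DataFrame:
    """Per-participant mean valence and arousal."""
    df = _as_frame(ratings)
    return df.groupby("participant_id")[["valence", "arousal"]].mean().sort_index()


def stimulus_means(ratings, midpoint: float = DEFAULT_MIDPOINT) -> pd.DataFrame:
    """Per-stimulus mean valence/arousal plus quadrant label."""
    df = _as_frame(ratings)
    means = df.groupby("stimulus_id")[["valence", "arousal"]].mean().sort_index()
    means["quadrant"] = [
        classify_quadrant(v, a, midpoint) for v, a in zip(means["valence"], means["arousal"])
    ]
    return means


def hvha_deviation(
    ratings,
    midpoint: float = DEFAULT_MIDPOINT,
    agg: str = "mean",
) -> pd.Series:
    """Per-participant signed arousal deviation over HVHA stimuli.

    Participants missing a rating for an HVHA stimulus are averaged over
    the HVHA stimuli they did rate.  ``agg`` may be ``mean`` (default),
    ``sum`` or ``median``.
    """
    if agg not in ("mean", "sum", "median"):
        raise ValidationError(f"unknown aggregation: {agg!r}")
    df = _as_frame(ratings)
    smeans = stimulus_means(df, midpoint)
    hvha = smeans.index[smeans["quadrant"] == "HVHA"]
    if len(hvha) == 0:
        raise ValidationError(
            "no stimulus classified HVHA; inspect stimulus_means() quadrants"
        )
    sub = df[df["stimulus_id"].isin(hvha)].copy()
    sub["deviation"] = sub["arousal"] - sub["stimulus_id"].map(smeans["arousal"])
    out = sub.groupby("participant_id")["deviation"].agg(agg).sort_index()
    out.name = "hvha_deviation"
    return out
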