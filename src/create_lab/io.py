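"""Stable on-disk formats for the pipeline.

All files are UTF-8 comma-separated with a header row, ISO-8601
timestamps, and empty string for missing values.  Floats are written with
repr-stable formatting so that repeated runs under the same seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic_cohort import EyeSignal, SyntheticCohort
from .wm_game import TrialRecord

__all__ = [
    "write_cohort",
    "read_wm_trials",
    "read_art_ratings",
    "read_questionnaires",
    "read_eye_signals",
    "write_table",
]

WM_TRIALS_FILE = "wm_trials.csv"
ART_RATINGS_FILE = "art_ratings.csv"
QUESTIONNAIRES_FILE = "questionnaires.csv"
EYE_SIGNALS_FILE = "eye_signals.csv"
EYE_SESSIONS_FILE = "eye_sessions.csv"
TRUTH_FILE = "truth.json"

_FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the four modality CSVs, the eye-session index, and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trial_rows = []
    for part in cohort.participants:
        for rec in part.trials:
            trial_rows.append(
                {
                    "participant_id": part.participant_id,
                    "trial_index": rec.trial_index,
                    "level": rec.level,
                    "display_duration_ms": rec.display_duration_ms,
                    "correct": int(rec.correct),
                    "running_score": rec.running_score,
                    "timestamp": rec.timestamp,
                }
            )
    paths["wm_trials"] = outdir / WM_TRIALS_FILE
    write_table(pd.DataFrame(trial_rows), paths["wm_trials"])

    rating_rows = []
    for part in cohort.participants:
        for r in part.ratings:
            rating_rows.append(
                {
                    "participant_id": r.participant_id,
                    "stimulus_id": r.stimulus_id,
                    "presentation_index": r.presentation_index,
                    "arousal": r.arousal,
                    "valence": r.valence,
                    "familiarity": r.familiarity,
                    "comment": r.comment,
                    "timestamp": r.timestamp,
                }
            )
    paths["art_ratings"] = outdir / ART_RATINGS_FILE
    write_table(pd.DataFrame(rating_rows), paths["art_ratings"])

    q_rows = []
    for part in cohort.participants:
        for item, resp in part.psqi_responses.items():
            q_rows.append(
                {
                    "participant_id": part.participant_id,
                    "instrument": "PSQI",
                    "item_id": item,
                    "response": resp,
                }
            )
        for item, resp in part.erq_responses.items():
            q_rows.append(
                {
                    "participant_id": part.participant_id,
                    "instrument": "ERQ",
                    "item_id": item,
                    "response": resp,
                }
            )
    paths["questionnaires"] = outdir / QUESTIONNAIRES_FILE
    write_table(pd.DataFrame(q_rows), paths["questionnaires"])

    signal_rows = []
    session_rows = []
    for part in cohort.participants:
        for phase, sig in (("pre", part.eye_pre), ("post", part.eye_post)):
            session_rows.append(
                {
                    "participant_id": part.participant_id,
                    "phase": phase,
                    "fps": sig.fps,
                    "n_frames": sig.ratio.size,
                }
            )
            signal_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": part.participant_id,
                        "phase": phase,
                        "frame": np.arange(sig.ratio.size),
                        "ratio": sig.ratio,
                    }
                )
            )
    paths["eye_sessions"] = outdir / EYE_SESSIONS_FILE
    write_table(pd.DataFrame(session_rows), paths["eye_sessions"])
    paths["eye_signals"] = outdir / EYE_SIGNALS_FILE
    write_table(pd.concat(signal_rows, ignore_index=True), paths["eye_signals"])

    paths["truth"] = outdir / TRUTH_FILE
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _require(path: Path, label: str) -> Path:
    if not path.exists():
        raise ValidationError(f"missing input file: {label} ({path})")
    return path


def read_wm_trials(path) -> dict[str, list[TrialRecord]]:
    """Per-participant ordered trial logs from wm_trials.csv."""
    df = pd.read_csv(_require(Path(path), "wm_trials"))
    out: dict[str, list[TrialRecord]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        out[str(pid)] = [
            TrialRecord(
                trial_index=int(r.trial_index),
                level=int(r.level),
                display_duration_ms=int(r.display_duration_ms),
                correct=bool(int(r.correct)),
                running_score=float(r.running_score),
                timestamp=str(r.timestamp),
            )
            for r in grp.itertuples()
        ]
    return out


def read_art_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(_require(Path(path), "art_ratings"))
    df["comment"] = df["comment"].fillna("")
    return df


def read_questionnaires(path) -> dict[str, dict[str, dict[str, object]]]:
    """{participant_id: {"PSQI": {...items}, "ERQ": {...items}}}."""
    df = pd.read_csv(_require(Path(path), "questionnaires"), dtype={"response": str})
    out: dict[str, dict[str, dict[str, object]]] = {}
    for row in df.itertuples():
        resp = "" if pd.isna(row.response) else str(row.response)
        out.setdefault(str(row.participant_id), {}).setdefault(str(row.instrument), {})[
            str(row.item_id)
        ] = resp
    return out


def read_eye_signals(signals_path, sessions_path) -> dict[str, dict[str, EyeSignal]]:
    """{participant_id: {"pre": EyeSignal, "post": EyeSignal}}."""
    sessions = pd.read_csv(_require(Path(sessions_path), "eye_sessions"))
    signals = pd.read_csv(_require(Path(signals_path), "eye_signals"))
    out: dict[str, dict[str, EyeSignal]] = {}
    grouped = signals.groupby(["participant_id", "phase"], sort=True)
    fps_map = {
        (str(r.participant_id), str(r.phase)): float(r.fps) for r in sessions.itertuples()
    }
    for (pid, phase), grp in grouped:
        key = (str(pid), str(phase))
        if key not in fps_map:
            raise ValidationError(f"eye signal for {key} has no session metadata row")
        ratio = grp.sort_values("frame")["ratio"].to_numpy()
        out.setdefault(str(pid), {})[str(phase)] = EyeSignal(ratio=ratio, fps=fps_map[key])
    return out
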