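"""Synthetic study cohorts with planted, recoverable statistical structure.

Latent participant traits (WM capacity, emotion-regulation level, sleep
quality, dopaminergic tone) are drawn from a Gaussian copula with a
configurable correlation matrix and mapped monotonically to the four
observable modalities:

* trait -> recall agent -> adaptive-game trial log (``wm_game``),
* trait -> PSQI / ERQ item responses (``psychometrics``),
* trait -> narrative polarity/subjectivity targets -> generated comments
  (closed loop through ``sentiment_text``),
* trait + sleep group -> planted blink counts -> eye-opening signals
  (``blink_sebr`` recovers them exactly by construction).

Planted ground truth (trait values, blink onset times, targets) is always
emitted alongside the data so downstream tests compare pipeline output to
truth rather than to any cohort-specific published value.  Everything is
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .affect_space import RatingRecord
from .errors import ValidationError
from .sentiment_text import SentimentLexicon, load_default_lexicon, tokenize
from .wm_game import AgentModel, GameConfig, TrialRecord, simulate_session

__all__ = [
    "TRAIT_NAMES",
    "TextParams",
    "CohortConfig",
    "EyeSignal",
    "ParticipantBundle",
    "SyntheticCohort",
    "sample_latent_traits",
    "generate_eye_signal",
    "generate_narrative",
    "psqi_responses_for_global",
    "generate_cohort",
]

TRAIT_NAMES = ("wm", "er", "sleep", "dopamine")

_BASE_TIME = datetime(2025, 1, 1, 10, 0, 0)

#: Neutral filler vocabulary for narrative generation.  Kept disjoint from
#: the lexicon entries and negators so filler words never score.
FILLER_WORDS = (
    "the", "a", "an", "of", "and", "in", "on", "with", "this", "that",
    "there", "here", "it", "its", "is", "was", "are", "image", "picture",
    "painting", "canvas", "scene", "figure", "figures", "line", "edges",
    "shapes", "palette", "tones", "brushwork", "surface", "foreground",
    "background", "composition", "landscape", "portrait", "sky", "water",
    "field", "shadow", "contrast", "person", "crowd", "building", "garden",
    "window", "table", "horizon",
)

_DEFAULT_LATENT_CORR = (
    (1.0, 0.5, 0.3, 0.2),
    (0.5, 1.0, 0.4, 0.2),
    (0.3, 0.4, 1.0, 0.3),
    (0.2, 0.2, 0.3, 1.0),
)


@dataclass(frozen=True)
class TextParams:
    """Per-participant narrative target schedule (coupled to the ER trait)."""

    polarity_center: float = 0.15
    polarity_span: float = 0.3
    subjectivity_center: float = 0.55
    subjectivity_span: float = 0.2
    tokens_min: int = 6
    tokens_max: int = 18
    tolerance: float = 0.12


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 27
    latent_corr: Sequence[Sequence[float]] = _DEFAULT_LATENT_CORR
    good_sleeper_fraction: float = 1.0 / 3.0
    #: group -> (pre, post) mean blink counts per session
    sebr_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"good": (33.0, 42.0), "poor": (94.0, 94.0)}
    )
    text_params: TextParams = TextParams()
    n_stimuli: int = 15
    seed: int = 0
    n_trials: int = 40
    eye_duration_s: float = 60.0
    fps: float = 30.0
    psqi_threshold: int = 5
    #: monotone link from the WM trait to an individual arousal-rating bias;
    #: negative values plant the deviation -> mean-score regression effect.
    arousal_wm_coupling: float = -0.4

    def corr_matrix(self) -> np.ndarray:
        corr = np.asarray(self.latent_corr, dtype=float)
        if corr.shape != (len(TRAIT_NAMES), len(TRAIT_NAMES)):
            raise ValidationError(
                f"latent_corr must be {len(TRAIT_NAMES)}x{len(TRAIT_NAMES)}"
            )
        if not np.allclose(corr, corr.T):
            raise ValidationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValidationError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValidationError("latent_corr is not positive semi-definite")
        return corr

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        if not 0.0 <= self.good_sleeper_fraction <= 1.0:
            raise ValidationError("good_sleeper_fraction must be in [0,1]")
        if self.n_stimuli < 1:
            raise ValidationError("n_stimuli must be >= 1")
        self.corr_matrix()


@dataclass(frozen=True)
class EyeSignal:
    ratio: np.ndarray
    fps: float


@dataclass(frozen=True)
class ParticipantBundle:
    participant_id: str
    psqi_responses: dict[str, object]
    erq_responses: dict[str, int]
    trials: list[TrialRecord]
    ratings: list[RatingRecord]
    eye_pre: EyeSignal
    eye_post: EyeSignal


@dataclass(frozen=True)
class SyntheticCohort:
    config: CohortConfig
    participants: list[ParticipantBundle]
    truth: dict


# ---------------------------------------------------------------------------
# Latent traits
# ---------------------------------------------------------------------------

def sample_latent_traits(
    n: int,
    corr: Sequence[Sequence[float]] | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw n rows from a Gaussian copula with the given trait correlation."""
    corr = np.asarray(corr, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-10:
        raise ValidationError("correlation matrix is not positive semi-definite")
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, corr.shape[0])) @ root.T


# ---------------------------------------------------------------------------
# Eye-opening signals with planted blink events
# ---------------------------------------------------------------------------

def generate_eye_signal(
    rate: int,
    duration: float,
    fps: float,
    seed: int | np.random.Generator,
    baseline: float = 1.0,
    dip_value: float = 0.1,
    dip_frames: int = 5,
    noise: float = 0.02,
    min_gap_frames: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Eye-opening-ratio series with ``rate`` planted blink dips.

    Returns (signal, onset frames).  Dips drop to ``dip_value`` for
    ``dip_frames`` frames; separation between onsets always exceeds the
    default detector's refractory period.  Bounded uniform noise keeps the
    open-eye baseline above and the dips below the default detection
    thresholds, so the default detector recovers the planted count exactly.
    """
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if duration <= 0 or fps <= 0:
        raise ValidationError("duration and fps must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = int(round(duration * fps))
    if min_gap_frames is None:
        min_gap_frames = max(int(np.ceil(100.0 * fps / 1000.0)) + 1, 3)
    sep = dip_frames + min_gap_frames
    signal = baseline + rng.uniform(-noise, noise, size=frames)
    if rate == 0:
        return signal, []
    n_slots = (frames - 1) // sep
    if rate > n_slots:
        raise ValidationError(
            f"rate {rate} too high for {duration}s at {fps}fps with separation "
            f"{sep} frames (max {n_slots} events)"
        )
    slots = np.sort(rng.choice(n_slots, size=rate, replace=False))
    onsets = (slots * sep + 1).tolist()
    for onset in onsets:
        signal[onset : onset + dip_frames] = dip_value + rng.uniform(
            -noise, noise, size=min(dip_frames, frames - onset)
        )
    return signal, onsets


# ---------------------------------------------------------------------------
# Narrative generation (closed loop through sentiment_text)
# ---------------------------------------------------------------------------

def generate_narrative(
    polarity_target: float,
    subjectivity_target: float,
    n_tokens: int,
    seed: int | np.random.Generator,
    lexicon: SentimentLexicon | None = None,
    tolerance: float = 0.12,
) -> str:
    """Compose a short text whose lexicon polarity/subjectivity hit targets.

    Lexicon words are chosen greedily so their running mean weights track
    the targets; remaining tokens are neutral filler that never scores.
    Targets of exactly (0, 0) produce all-filler text.  Unreachable targets
    raise a validation error naming the feasible range.
    """
    if not -1.0 <= polarity_target <= 1.0:
        raise ValidationError(f"polarity target outside [-1,1]: {polarity_target}")
    if not 0.0 <= subjectivity_target <= 1.0:
        raise ValidationError(f"subjectivity target outside [0,1]: {subjectivity_target}")
    if n_tokens < 1:
        raise ValidationError("n_tokens must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lexicon = lexicon or load_default_lexicon()
    fillers = [w for w in FILLER_WORDS if w not in lexicon.entries and w not in lexicon.negators]

    if polarity_target == 0.0 and subjectivity_target == 0.0:
        return " ".join(rng.choice(fillers, size=n_tokens))

    pmin, pmax = lexicon.polarity_range
    smin, smax = lexicon.subjectivity_range
    if not (pmin <= polarity_target <= pmax and smin <= subjectivity_target <= smax):
        raise ValidationError(
            f"target ({polarity_target}, {subjectivity_target}) outside feasible "
            f"lexicon range: polarity [{pmin}, {pmax}], subjectivity [{smin}, {smax}]"
        )

    n_lex = max(1, min(n_tokens, int(round(n_tokens * 0.6))))
    entries = sorted(lexicon.entries.items())  # stable order for determinism
    chosen: list[str] = []
    sum_p = sum_s = 0.0
    for i in range(n_lex):
        m = i + 1
        scores = [
            abs((sum_p + p) / m - polarity_target) + abs((sum_s + s) / m - subjectivity_target)
            for _, (p, s) in entries
        ]
        order = np.argsort(scores, kind="stable")
        # sample among near-ties early for lexical variety; lock in exactly
        # at the end so the running means land on target
        top = order[: 5 if i < n_lex - 2 else 1]
        pick = int(top[rng.integers(len(top))])
        word, (p, s) = entries[pick]
        chosen.append(word)
        sum_p += p
        sum_s += s

    achieved_p, achieved_s = sum_p / n_lex, sum_s / n_lex
    if abs(achieved_p - polarity_target) > tolerance or abs(achieved_s - subjectivity_target) > tolerance:
        raise ValidationError(
            f"joint target ({polarity_target}, {subjectivity_target}) unreachable "
            f"within tolerance {tolerance}; closest achieved ({achieved_p:.3f}, "
            f"{achieved_s:.3f}); feasible marginals: polarity [{pmin}, {pmax}], "
            f"subjectivity [{smin}, {smax}]"
        )

    tokens = chosen + list(rng.choice(fillers, size=n_tokens - n_lex))
    rng.shuffle(tokens)
    text = " ".join(tokens)
    assert len(tokenize(text)) == n_tokens
    return text


# ---------------------------------------------------------------------------
# Questionnaire item generation
# ---------------------------------------------------------------------------

_LATENCY_BY_COMPONENT = {0: (10, 0), 1: (20, 0), 2: (45, 1), 3: (90, 2)}
_HOURS_BY_COMPONENT = {0: 8.0, 1: 6.5, 2: 5.5, 3: 4.5}
_EFFICIENCY_BY_COMPONENT = {0: 0.95, 1: 0.80, 2: 0.70, 3: 0.55}
_DISTURB_SUM_BY_COMPONENT = {0: 0, 1: 5, 2: 14, 3: 22}
_DAYTIME_BY_COMPONENT = {0: (0, 0), 1: (1, 0), 2: (2, 1), 3: (3, 3)}


def _component_targets(global_target: int) -> list[int]:
    base, rem = divmod(int(global_target), 7)
    return [base + 1 if i < rem else base for i in range(7)]


def psqi_responses_for_global(global_target: int) -> dict[str, object]:
    """Deterministic 19-item response sheet scoring exactly ``global_target``.

    Inverts the component banding rules: the target is spread over the
    seven components and each component is realized by mid-band item values.
    """
    if not 0 <= global_target <= 21:
        raise ValidationError(f"global target outside [0,21]: {global_target}")
    c1, c2, c3, c4, c5, c6, c7 = _component_targets(global_target)
    latency_min, q5a = _LATENCY_BY_COMPONENT[c2]
    hours = _HOURS_BY_COMPONENT[c3]
    in_bed_min = int(round(hours / _EFFICIENCY_BY_COMPONENT[c4] * 60))
    bedtime = datetime(2025, 1, 1, 23, 0)
    waketime = bedtime + timedelta(minutes=in_bed_min)
    dist_sum = _DISTURB_SUM_BY_COMPONENT[c5]
    disturb: dict[str, int] = {}
    remaining = dist_sum
    for ch in "bcdefghij":
        v = min(3, remaining)
        disturb[f"q5{ch}"] = v
        remaining -= v
    q8, q9 = _DAYTIME_BY_COMPONENT[c7]
    return {
        "q1_bedtime": bedtime.strftime("%H:%M"),
        "q2_latency_min": latency_min,
        "q3_waketime": waketime.strftime("%H:%M"),
        "q4_sleep_hours": hours,
        "q5a": q5a,
        **disturb,
        "q5j_desc": "",
        "q6_quality": c1,
        "q7_medication": c6,
        "q8_sleepy": q8,
        "q9_enthusiasm": q9,
    }


def _psqi_global_target(u_good: float, good_fraction: float) -> int:
    """Map a uniform sleep-trait percentile to a global-score target.

    Monotone decreasing in ``u_good`` (higher percentile = better sleep);
    the resulting global lands at <= 5 (Good) with probability exactly
    ``good_fraction``.
    """
    if good_fraction >= 1.0:
        return int(round(5 * (1.0 - u_good)))
    if good_fraction <= 0.0:
        return 6 + int(round(15 * (1.0 - u_good)))
    if u_good > 1.0 - good_fraction:
        frac = (u_good - (1.0 - good_fraction)) / good_fraction
        return int(round(5 * (1.0 - frac)))
    frac = u_good / (1.0 - good_fraction)
    return 6 + int(round(15 * (1.0 - frac)))


def _erq_responses(z_er: float, rng: np.random.Generator) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(1, 11):
        center = 5.0 if i in (1, 3, 5, 7, 8, 10) else 3.0
        val = int(round(center + 1.0 * z_er + rng.normal(0.0, 0.8)))
        out[f"item{i}"] = int(np.clip(val, 1, 7))
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _stimulus_centers(n_stimuli: int, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Cycle the four affect quadrants so every cohort has HVHA stimuli."""
    quadrants = ("HVHA", "LVHA", "LVLA", "HVLA")
    centers: dict[str, tuple[float, float]] = {}
    for i in range(n_stimuli):
        quad = quadrants[i % 4]
        high_v = quad[0] == "H"
        high_a = quad[2] == "H"
        v = rng.uniform(6.5, 9.0) if high_v else rng.uniform(2.0, 4.5)
        a = rng.uniform(6.5, 9.0) if high_a else rng.uniform(2.0, 4.5)
        centers[f"stim{i + 1:02d}"] = (v, a)
    return centers


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one complete synthetic study dataset plus ground truth."""
    config.validate()
    corr = config.corr_matrix()
    root_ss = np.random.SeedSequence(config.seed)
    traits_ss, stim_ss, participants_ss = root_ss.spawn(3)

    traits = sample_latent_traits(
        config.n_participants, corr, np.random.default_rng(traits_ss)
    )
    centers = _stimulus_centers(config.n_stimuli, np.random.default_rng(stim_ss))
    stim_ids = sorted(centers)

    rates = {k.lower(): tuple(v) for k, v in config.sebr_rates.items()}
    if not {"good", "poor"} <= set(rates):
        raise ValidationError("sebr_rates must define 'good' and 'poor' groups")

    frames = int(round(config.eye_duration_s * config.fps))
    sep = 5 + max(int(np.ceil(100.0 * config.fps / 1000.0)) + 1, 3)
    max_rate = (frames - 1) // sep

    participants: list[ParticipantBundle] = []
    truth: dict = {
        "seed": config.seed,
        "trait_names": list(TRAIT_NAMES),
        "participants": {},
        "stimulus_centers": {
            sid: {"valence": v, "arousal": a} for sid, (v, a) in centers.items()
        },
    }

    for idx, part_ss in enumerate(participants_ss.spawn(config.n_participants)):
        pid = f"p{idx + 1:03d}"
        z_wm, z_er, z_sleep, z_d = traits[idx]
        (game_ss, erq_ss, rating_ss, text_ss, pre_ss, post_ss) = part_ss.spawn(6)

        # --- working-memory session
        agent = AgentModel(capacity=9.0 + 2.5 * z_wm, slope=1.0, lapse=0.02)
        trials = simulate_session(
            agent, GameConfig(), config.n_trials, np.random.default_rng(game_ss)
        )

        # --- questionnaires
        u_good = float(norm.cdf(z_sleep))
        global_target = _psqi_global_target(u_good, config.good_sleeper_fraction)
        psqi = psqi_responses_for_global(global_target)
        good = global_target <= config.psqi_threshold
        erq = _erq_responses(z_er, np.random.default_rng(erq_ss))

        # --- blink sessions
        group = "good" if good else "poor"
        pre_mean, post_mean = rates[group]
        factor = 1.0 + 0.25 * z_d
        rate_pre = int(np.clip(round(pre_mean * factor), 0, max_rate))
        rate_post = int(np.clip(round(post_mean * factor), 0, max_rate))
        sig_pre, onsets_pre = generate_eye_signal(
            rate_pre, config.eye_duration_s, config.fps, np.random.default_rng(pre_ss)
        )
        sig_post, onsets_post = generate_eye_signal(
            rate_post, config.eye_duration_s, config.fps, np.random.default_rng(post_ss)
        )

        # --- art ratings with narratives
        tp = config.text_params
        u_er = float(norm.cdf(z_er))
        pol_target = float(
            np.clip(tp.polarity_center + tp.polarity_span * (2 * u_er - 1), -1.0, 1.0)
        )
        subj_target = float(
            np.clip(tp.subjectivity_center + tp.subjectivity_span * (2 * u_er - 1), 0.0, 1.0)
        )
        rating_rng = np.random.default_rng(rating_ss)
        text_rng = np.random.default_rng(text_ss)
        order = rating_rng.permutation(len(stim_ids))
        arousal_bias = config.arousal_wm_coupling * z_wm
        ratings: list[RatingRecord] = []
        for pres_idx, stim_pos in enumerate(order, start=1):
            sid = stim_ids[stim_pos]
            v_center, a_center = centers[sid]
            valence = int(np.clip(round(v_center + rating_rng.normal(0, 1.0)), 1, 10))
            arousal = int(
                np.clip(round(a_center + arousal_bias + rating_rng.normal(0, 1.0)), 1, 10)
            )
            familiarity = int(rating_rng.integers(1, 11))
            n_tok = int(text_rng.integers(tp.tokens_min, tp.tokens_max + 1))
            comment = generate_narrative(
                pol_target, subj_target, n_tok, text_rng, tolerance=tp.tolerance
            )
            ratings.append(
                RatingRecord(
                    participant_id=pid,
                    stimulus_id=sid,
                    arousal=arousal,
                    valence=valence,
                    familiarity=familiarity,
                    comment=comment,
                    timestamp=(_BASE_TIME + timedelta(seconds=30 * pres_idx)).isoformat(),
                    presentation_index=pres_idx,
                )
            )

        participants.append(
            ParticipantBundle(
                participant_id=pid,
                psqi_responses=psqi,
                erq_responses=erq,
                trials=trials,
                ratings=ratings,
                eye_pre=EyeSignal(ratio=sig_pre, fps=config.fps),
                eye_post=EyeSignal(ratio=sig_post, fps=config.fps),
            )
        )
        truth["participants"][pid] = {
            "traits": {name: float(z) for name, z in zip(TRAIT_NAMES, traits[idx])},
            "good_sleeper": bool(good),
            "psqi_global_target": int(global_target),
            "agent_capacity": agent.capacity,
            "text_targets": {"polarity": pol_target, "subjectivity": subj_target},
            "blink_onsets": {"pre": onsets_pre, "post": onsets_post},
            "blink_counts": {"pre": rate_pre, "post": rate_post},
        }

    return SyntheticCohort(config=config, participants=participants, truth=truth)
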