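"""Lexicon-based narrative features for free-text stimulus comments.

Six per-comment features are computed: polarity, subjectivity, average
word length, token count, unique tokens, and type-token ratio.  Polarity
and subjectivity come from a transparent packaged lexicon (word ->
(polarity, subjectivity) weights) so that every score is auditable and
reproducible; no external model is consulted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "SentimentLexicon",
    "TextFeatures",
    "load_default_lexicon",
    "tokenize",
    "lexical_features",
    "polarity_subjectivity",
    "text_features",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

#: Words that flip the polarity of the immediately following lexicon match.
DEFAULT_NEGATORS = frozenset(
    {
        "not",
        "no",
        "never",
        "hardly",
        "neither",
        "nor",
        "cannot",
        "cant",
        "dont",
        "didnt",
        "doesnt",
        "isnt",
        "wasnt",
        "wont",
        "without",
    }
)


@dataclass(frozen=True)
class SentimentLexicon:
    """Word -> (polarity, subjectivity) table with a one-token negation rule."""

    entries: Mapping[str, tuple[float, float]]
    negators: frozenset[str] = DEFAULT_NEGATORS
    negation_factor: float = -0.5

    def __post_init__(self) -> None:
        for word, (pol, subj) in self.entries.items():
            if not -1.0 <= pol <= 1.0:
                raise ValidationError(f"polarity weight out of [-1,1] for {word!r}: {pol}")
            if not 0.0 <= subj <= 1.0:
                raise ValidationError(f"subjectivity weight out of [0,1] for {word!r}: {subj}")
        overlap = set(self.entries) & set(self.negators)
        if overlap:
            raise ValidationError(f"negators overlap lexicon entries: {sorted(overlap)}")

    @property
    def polarity_range(self) -> tuple[float, float]:
        pols = [p for p, _ in self.entries.values()]
        return (min(pols), max(pols))

    @property
    def subjectivity_range(self) -> tuple[float, float]:
        subs = [s for _, s in self.entries.values()]
        return (min(subs), max(subs))

    @classmethod
    def from_file(cls, path, **kwargs) -> "SentimentLexicon":
        entries: dict[str, tuple[float, float]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, pol, subj = line.split()
                entries[word] = (float(pol), float(subj))
        return cls(entries=entries, **kwargs)


@lru_cache(maxsize=1)
def load_default_lexicon() -> SentimentLexicon:
    """Load the lexicon shipped with the package (data/lexicon.txt)."""
    ref = resources.files("create_lab.data").joinpath("lexicon.txt")
    with resources.as_file(ref) as path:
        return SentimentLexicon.from_file(path)


@dataclass(frozen=True)
class TextFeatures:
    polarity: float
    subjectivity: float
    avg_word_length: float  # NaN for empty input
    token_count: int
    unique_tokens: int
    type_token_ratio: float  # NaN for empty input

    def as_dict(self) -> dict[str, float]:
        return {
            "polarity": self.polarity,
            "subjectivity": self.subjectivity,
            "avg_word_length": self.avg_word_length,
            "token_count": self.token_count,
            "unique_tokens": self.unique_tokens,
            "type_token_ratio": self.type_token_ratio,
        }


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def lexical_features(tokens: Sequence[str]) -> tuple[int, int, float, float]:
    """Return (token_count, unique_tokens, type_token_ratio, avg_word_length).

    The ratio and average length are NaN (missing) for an empty token list;
    they are never coerced to zero.
    """
    n = len(tokens)
    uniq = len(set(tokens))
    if n == 0:
        return 0, 0, math.nan, math.nan
    ttr = uniq / n
    awl = sum(len(t) for t in tokens) / n
    return n, uniq, ttr, awl


def polarity_subjectivity(
    tokens: Sequence[str], lexicon: SentimentLexicon | None = None
) -> tuple[float, float]:
    """Mean lexicon polarity (negation-adjusted) and mean subjectivity.

    A matched word immediately preceded by a negator has its polarity
    multiplied by ``negation_factor``; subjectivity is unaffected.  With no
    matches both scores default to 0.0 (neutral).
    """
    lexicon = lexicon or load_default_lexicon()
    pols: list[float] = []
    subs: list[float] = []
    for i, tok in enumerate(tokens):
        weights = lexicon.entries.get(tok)
        if weights is None:
            continue
        pol, subj = weights
        if i > 0 and tokens[i - 1] in lexicon.negators:
            pol *= lexicon.negation_factor
        pols.append(pol)
        subs.append(subj)
    if not pols:
        return 0.0, 0.0
    return sum(pols) / len(pols), sum(subs) / len(subs)


def text_features(text: str, lexicon: SentimentLexicon | None = None) -> TextFeatures:
    """All six features for one comment string."""
    tokens = tokenize(text)
    count, uniq, ttr, awl = lexical_features(tokens)
    pol, subj = polarity_subjectivity(tokens, lexicon)
    return TextFeatures(
        polarity=pol,
        subjectivity=subj,
        avg_word_length=awl,
        token_count=count,
        unique_tokens=uniq,
        type_token_ratio=ttr,
    )
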