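"""Text preprocessing: from raw forum posts to stemmed unigram/bigram tokens.

The pipeline applies, in order: dosage-mention standardization (before
tokenization, while the number and its unit are still contiguous),
lowercasing and punctuation stripping, stopword removal, removal of the
drug name that defined the corpus, French Snowball stemming, and n-gram
construction (unigrams plus adjacent bigrams).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._snowball import stem_word
from .corpus import Message, RunConfig

__all__ = [
    "DOSE_TOKEN",
    "DEFAULT_DOSAGE_UNITS",
    "TokenizedDocument",
    "standardize_dosage",
    "tokenize",
    "remove_stopwords",
    "remove_drug_mentions",
    "stem",
    "build_ngrams",
    "preprocess_message",
    "preprocess_corpus",
]

#: Neutral replacement for every dosage mention (e.g. "10 mg", "2,5mg").
DOSE_TOKEN = "dosemilligrams"

DEFAULT_DOSAGE_UNITS = (
    "milligrammes", "milligramme", "milligrams", "milligram",
    "grammes", "gramme", "mcg", "µg", "mg", "ml", "g",
)


@dataclass(frozen=True)
class TokenizedDocument:
    """Preprocessed message: its id and the final token sequence."""

    message_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def _dosage_pattern(units: Sequence[str]) -> re.Pattern:
    # longest units first so "mg" does not shadow "milligramme"
    alts = "|".join(re.escape(u) for u in sorted(units, key=len, reverse=True))
    return re.compile(rf"\d+(?:[.,]\d+)?\s*(?:{alts})\b", re.IGNORECASE)


_DEFAULT_DOSE_RE = _dosage_pattern(DEFAULT_DOSAGE_UNITS)


def standardize_dosage(text: str, units: Sequence[str] | None = None) -> str:
    """Replace every ``<number><optional space><unit>`` mention by
    :data:`DOSE_TOKEN`.

    Numbers may use ``.`` or ``,`` decimals; the unit list is configurable.
    All other characters are left unchanged.
    """
    pattern = _DEFAULT_DOSE_RE if units is None else _dosage_pattern(units)
    return pattern.sub(DOSE_TOKEN, text)


def _is_word_char(ch: str) -> bool:
    # letters and digits survive; every punctuation mark (incl. apostrophes,
    # so French elisions split) and symbol becomes a separator
    return unicodedata.category(ch)[0] in ("L", "N")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace and punctuation.

    Apostrophes separate (``l'arrêt`` → ``l``, ``arrêt``); the empty or
    all-punctuation string yields an empty list.
    """
    lowered = text.lower()
    cleaned = "".join(ch if _is_word_char(ch) else " " for ch in lowered)
    return cleaned.split()


def remove_stopwords(tokens: Iterable[str], stopwords: set[str]) -> list[str]:
    """Order-preserving exact-membership stopword filter."""
    return [t for t in tokens if t not in stopwords]


def remove_drug_mentions(tokens: Iterable[str], drug_names: set[str]) -> list[str]:
    """Drop tokens exactly matching a configured drug name.

    The drug name defined the corpus, so it appears in every message and
    carries no information.  Matching is exact: misspellings are retained
    (fuzzy matching is out of scope).
    """
    return [t for t in tokens if t not in drug_names]


def stem(tokens: Iterable[str],
         protected: frozenset[str] = frozenset({DOSE_TOKEN})) -> list[str]:
    """Stem each token with the French Snowball stemmer.

    Tokens in ``protected`` (by default the dosage placeholder) pass
    through unchanged.
    """
    return [t if t in protected else stem_word(t) for t in tokens]


def build_ngrams(tokens: Sequence[str],
                 orders: frozenset[int] = frozenset({1, 2})) -> list[str]:
    """Unigrams in order, then adjacent bigrams joined with ``_``.

    Adjacency is measured in the filtered, stemmed sequence.
    """
    out: list[str] = []
    if 1 in orders:
        out.extend(tokens)
    if 2 in orders:
        out.extend(f"{a}_{b}" for a, b in zip(tokens, tokens[1:]))
    return out


def preprocess_message(
    msg: Message,
    config: RunConfig,
    stopwords: set[str] | None = None,
    dosage_units: Sequence[str] | None = None,
) -> TokenizedDocument:
    """Run the full preprocessing pipeline on one message.

    ``stopwords`` may be passed to avoid re-reading the lexicon per
    message; otherwise it is resolved from the config.
    """
    if stopwords is None:
        stopwords = config.stopwords()
    text = standardize_dosage(msg.text, dosage_units)
    tokens = tokenize(text)
    tokens = remove_stopwords(tokens, stopwords)
    tokens = remove_drug_mentions(tokens, set(config.drug_names))
    tokens = stem(tokens)
    tokens = build_ngrams(tokens)
    return TokenizedDocument(message_id=msg.id, tokens=tuple(tokens))


def preprocess_corpus(
    messages: Iterable[Message],
    config: RunConfig,
    dosage_units: Sequence[str] | None = None,
) -> list[TokenizedDocument]:
    """Preprocess every message, resolving lexicons once."""
    stopwords = config.stopwords()
    return [preprocess_message(m, config, stopwords, dosage_units)
            for m in messages]
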