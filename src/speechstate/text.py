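"""Transcript cleaning and psycholinguistic feature extraction.

Transcripts are lowercased, stripped of punctuation and special characters,
tokenized on whitespace, POS-tagged and lemmatized against the packaged
lexicon (suffix rules back up unknown words).  From the tagged stream we
compute a propositional idea count (CPIDR-style POS-class rule), lexical
richness statistics (Honoré's R, Brunet's W), part-of-speech ratios, and
lexical-content measures — 17 features per transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .lexicon import (AUX_WORDS, DEFINITES, FILLER_WORDS, INDEFINITES,
                      Lexicon, default_lexicon)

log = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z]+")

#: POS classes counted as propositions (verbs, adjectives, adverbs,
#: prepositions, conjunctions; modals count as verbs unless auxiliary).
_IDEA_TAGS = ("VB", "JJ", "RB", "IN", "CC", "MD")
_CONTENT_TAGS = ("NN", "VB", "JJ", "RB")

PSYCHOLINGUISTIC_FEATURES = (
    "Ideas", "W-Total", "Density",
    "N-Pronouns", "N-Nouns", "N-Verbs", "Determiners", "Indefinites",
    "Definites", "N-I",
    "Honores", "Brunets", "W-content", "W-Empty", "TypeToken", "Frequency",
    "Fillers",
)


@dataclass
class CleanTranscript:
    raw: str
    tokens: list[str]
    tags: list[str]
    lemmas: list[str]

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.tags) == len(self.lemmas)):
            raise ValueError("tokens, tags, and lemmas must align 1:1")


def clean_and_tag(raw: str, lexicon: Lexicon | None = None) -> CleanTranscript:
    """Lowercase, strip punctuation/special characters, tokenize, tag,
    lemmatize."""
    lex = lexicon or default_lexicon()
    tokens = _WORD_RE.findall(raw.lower())
    if not tokens:
        raise ValueError("transcript is empty after cleaning")
    tags = [lex.tag(t) for t in tokens]
    lemmas = [lex.lemmatize(t) for t in tokens]
    return CleanTranscript(raw=raw, tokens=tokens, tags=tags, lemmas=lemmas)


def count_propositions(transcript: CleanTranscript) -> int:
    """CPIDR-style idea count.

    Tokens whose tag class is verb, adjective, adverb, preposition, or
    conjunction each contribute one proposition, with two adjustments:
    determiners never count, and an auxiliary verb immediately preceding a
    verb does not count.
    """
    ideas = 0
    tags = transcript.tags
    for i, (tok, tag) in enumerate(zip(transcript.tokens, tags)):
        if tag.startswith("DT"):
            continue
        if not any(tag.startswith(c) for c in _IDEA_TAGS):
            continue
        nxt = tags[i + 1] if i + 1 < len(tags) else ""
        if tok in AUX_WORDS and (nxt.startswith("VB") or nxt == "MD"):
            continue
        ideas += 1
    return ideas


@dataclass
class LexicalProfile:
    n_tokens: int
    n_types: int
    n_hapax: int
    ideas: int
    density: float
    honore: float
    brunet: float
    content_words: int
    empty_words: int
    fillers: int
    mean_log_frequency: float

    def __post_init__(self) -> None:
        if not self.n_hapax <= self.n_types <= self.n_tokens:
            raise ValueError("hapax <= types <= tokens violated")


def honore_statistic(n: int, v: int, v1: int) -> float:
    """Honoré's R = 100 ln N / (1 - V1/V); undefined when every type is a
    hapax."""
    if v1 >= v:
        return np.nan
    return 100.0 * np.log(n) / (1.0 - v1 / v)


def brunet_index(n: int, v: int) -> float:
    """Brunet's W = N ** (V ** -0.165); lower values = richer vocabulary."""
    return float(n ** (v ** -0.165))


def _filler_count(tokens: list[str]) -> int:
    n = sum(1 for t in tokens if t in FILLER_WORDS)
    n += sum(1 for a, b in zip(tokens, tokens[1:]) if a == "you" and b == "know")
    return n


def lexical_stats(transcript: CleanTranscript,
                  frequency_table: dict[str, int] | None = None
                  ) -> LexicalProfile:
    """Lexical richness and content statistics for one transcript."""
    tokens = transcript.tokens
    n = len(tokens)
    if n < 1:
        raise ValueError("empty transcript")
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    v = len(counts)
    v1 = sum(1 for c in counts.values() if c == 1)
    honore = honore_statistic(n, v, v1)
    if np.isnan(honore):
        log.info("Honoré undefined (every type is a hapax)")

    content = sum(1 for tag in transcript.tags
                  if any(tag.startswith(c) for c in _CONTENT_TAGS))
    ideas = count_propositions(transcript)
    if frequency_table is None:
        frequency_table = default_frequency_table()
    mean_logf = float(np.mean([np.log1p(frequency_table.get(t, 0))
                               for t in tokens]))
    return LexicalProfile(
        n_tokens=n, n_types=v, n_hapax=v1, ideas=ideas, density=ideas / n,
        honore=honore, brunet=brunet_index(n, v), content_words=content,
        empty_words=n - content, fillers=_filler_count(tokens),
        mean_log_frequency=mean_logf,
    )


def extract_psycholinguistic(transcript: CleanTranscript,
                             frequency_table: dict[str, int] | None = None
                             ) -> dict[str, float]:
    """The 17 psycholinguistic features (counts, ratios, richness)."""
    prof = lexical_stats(transcript, frequency_table)
    n = prof.n_tokens
    tags = transcript.tags
    toks = transcript.tokens

    def ratio(pred) -> float:
        return sum(1 for t, g in zip(toks, tags) if pred(t, g)) / n

    feats = {
        "Ideas": float(prof.ideas),
        "W-Total": float(n),
        "Density": prof.density,
        "N-Pronouns": ratio(lambda t, g: g.startswith("PRP")),
        "N-Nouns": ratio(lambda t, g: g.startswith("NN")),
        "N-Verbs": ratio(lambda t, g: g.startswith("VB") or g == "MD"),
        "Determiners": ratio(lambda t, g: g.startswith("DT")),
        "Indefinites": ratio(lambda t, g: t in INDEFINITES),
        "Definites": ratio(lambda t, g: t in DEFINITES),
        "N-I": ratio(lambda t, g: t == "i"),
        "Honores": prof.honore,
        "Brunets": prof.brunet,
        "W-content": prof.content_words / n,
        "W-Empty": prof.empty_words / n,
        "TypeToken": prof.n_types / n,
        "Frequency": prof.mean_log_frequency,
        "Fillers": prof.fillers / n,
    }
    assert tuple(feats) == PSYCHOLINGUISTIC_FEATURES
    return feats


@lru_cache(maxsize=1)
def default_frequency_table() -> dict[str, int]:
    """Token counts over the packaged background corpus."""
    from .synth import generate_corpus

    table: dict[str, int] = {}
    for doc in generate_corpus():
        for t in doc:
            table[t] = table.get(t, 0) + 1
    return table
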