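"""Synthetic-English lexicon: a closed vocabulary with fixed POS tags.

The cohort generator writes transcripts in a small constructed language whose
every word carries a known part of speech, lemma, and topic assignment.  This
makes the tagging and lemmatization stages of the text pipeline fully
deterministic and self-contained: no external tagger model is needed to test
the feature extractors.  Real English function words, fillers, auxiliaries,
and the 21 concept words of interest are embedded verbatim so that cleaning,
proposition counting, and concept-proximity scoring behave as they would on
natural transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The 21 mental-state concept words scored by the semantic extractor.
CONCEPTS: tuple[str, ...] = (
    "affect", "anxiety", "compassion", "confidence", "disdain", "emotion",
    "empathy", "fear", "feeling", "forgive", "friend", "happy", "intimacy",
    "love", "pain", "peace", "rapport", "sad", "support", "think", "talk",
)

# POS for the embedded real words (Penn-Treebank-style tags).
_CONCEPT_POS = {
    "forgive": "VB", "support": "VB", "think": "VB", "talk": "VB",
    "happy": "JJ", "sad": "JJ",
}

_DETERMINERS = ("the", "a", "an", "this", "that", "these", "those",
                "some", "any", "each", "every", "no")
_PRONOUNS = ("i", "you", "he", "she", "it", "we", "they",
             "me", "him", "her", "us", "them", "my", "your", "our")
_PREPOSITIONS = ("of", "in", "on", "at", "with", "from", "to", "by",
                 "about", "over", "under", "for")
_CONJUNCTIONS = ("and", "but", "or", "so", "because")
_AUXILIARIES = ("is", "was", "are", "were", "be", "been", "am",
                "have", "has", "had", "do", "does", "did",
                "will", "would", "can", "could", "should", "might")
_ADVERBS = ("very", "really", "quite", "just", "now", "then", "here", "there")
_FILLERS = ("um", "uh", "er", "hmm", "like")

#: Closed word lists behind the indefinite/definite ratio features.
INDEFINITES = frozenset(
    {"a", "an", "some", "any", "one", "something", "anything",
     "someone", "anyone", "nothing"})
DEFINITES = frozenset({"the", "this", "that", "these", "those"})
FILLER_WORDS = frozenset(_FILLERS)
AUX_WORDS = frozenset(_AUXILIARIES)

# Small irregular lemma table so natural test phrases lemmatize sensibly.
_IRREGULAR_LEMMAS = {
    "ran": "run", "felt": "feel", "was": "be", "were": "be", "is": "be",
    "are": "be", "am": "be", "been": "be", "has": "have", "had": "have",
    "did": "do", "does": "do", "men": "man", "women": "woman",
    "feelings": "feeling", "friends": "friend", "dogs": "dog",
    "children": "child", "said": "say", "went": "go", "thought": "think",
    "talked": "talk", "loved": "love",
}
_IRREGULAR_POS = {
    "ran": "VBD", "felt": "VBD", "dogs": "NNS", "dog": "NN", "run": "VB",
    "feel": "VB", "man": "NN", "men": "NNS", "woman": "NN", "women": "NNS",
    "child": "NN", "children": "NNS", "say": "VB", "said": "VBD",
    "go": "VB", "went": "VBD", "thought": "VBD", "talked": "VBD",
    "loved": "VBD", "know": "VB", "people": "NNS", "person": "NN",
    "life": "NN", "time": "NN", "day": "NN", "good": "JJ", "new": "JJ",
    "tall": "JJ", "big": "JJ", "small": "JJ", "nice": "JJ",
}

_ONSETS = ("b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v",
           "w", "z", "bl", "br", "ch", "cl", "cr", "dr", "fl", "fr", "gl",
           "gr", "pl", "pr", "sh", "sk", "sl", "sm", "sn", "sp", "st", "tr")
_NUCLEI = ("a", "e", "i", "o", "u", "ai", "ea", "ee", "oo", "ou")
_CODAS = ("", "n", "r", "s", "t", "l", "m", "k", "nd", "nt", "st", "sh")

_LEXICON_SEED = 20200124  # fixed; the lexicon is a versioned constant
N_BACKGROUND_TOPICS = 12
_WORDS_PER_CONCEPT_TOPIC = 24   # plus the concept word itself
_WORDS_PER_BACKGROUND_TOPIC = 45
_POS_CYCLE = ("NN", "NN", "VB", "JJ", "NN", "VB", "RB", "NN")


@dataclass
class Lexicon:
    """Closed vocabulary with POS, lemma, and topic for every word."""

    pos: dict[str, str]
    lemma: dict[str, str]
    topic: dict[str, str]                 # content words only
    topics: dict[str, list[str]]          # topic -> member words (with weights order)
    topic_weights: dict[str, np.ndarray] = field(repr=False, default=None)
    version: str = "1"

    def __contains__(self, word: str) -> bool:
        return word in self.pos

    @property
    def background_topics(self) -> list[str]:
        return [t for t in self.topics if t.startswith("bg_")]

    def concept_topic(self, concept: str) -> str:
        name = f"c_{concept}"
        if name not in self.topics:
            raise KeyError(f"no concept topic for {concept!r}")
        return name

    def tag(self, token: str) -> str:
        """POS tag for a token; unknown words fall back to suffix rules."""
        if token in self.pos:
            return self.pos[token]
        if token.endswith("ing"):
            return "VBG"
        if token.endswith("ed"):
            return "VBD"
        if token.endswith("ly"):
            return "RB"
        if token.endswith("s"):
            return "NNS"
        return "NN"

    def lemmatize(self, token: str) -> str:
        """Lemma by lexicon lookup, irregular table, then suffix stripping."""
        if token in self.lemma:
            return self.lemma[token]
        if token in _IRREGULAR_LEMMAS:
            return _IRREGULAR_LEMMAS[token]
        for suffix in ("ing", "ed", "es", "s"):
            if token.endswith(suffix) and len(token) > len(suffix) + 2:
                return token[: -len(suffix)]
        return token

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tpos\tlemma\ttopic\n")
            for word in sorted(self.pos):
                fh.write(f"{word}\t{self.pos[word]}\t{self.lemma[word]}\t"
                         f"{self.topic.get(word, '-')}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        pos, lemma, topic = {}, {}, {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("word\t"):
                raise ValueError("lexicon TSV must start with a 'word' header")
            for line in fh:
                w, p, le, t = line.rstrip("\n").split("\t")
                pos[w], lemma[w] = p, le
                if t != "-":
                    topic[w] = t
        topics: dict[str, list[str]] = {}
        for w, t in topic.items():
            topics.setdefault(t, []).append(w)
        lex = cls(pos=pos, lemma=lemma, topic=topic, topics=topics)
        lex._finalize_weights()
        return lex

    def _finalize_weights(self) -> None:
        # Zipf-like sampling weight by within-topic rank (order of insertion).
        self.topic_weights = {}
        for t, words in self.topics.items():
            ranks = np.arange(1, len(words) + 1, dtype=float)
            w = 1.0 / ranks
            self.topic_weights[t] = w / w.sum()


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        syls = 2 if rng.random() < 0.7 else 3
        word = "".join(
            rng.choice(_ONSETS) + rng.choice(_NUCLEI) +
            (rng.choice(_CODAS) if s == syls - 1 else "")
            for s in range(syls)
        )
        if word in taken or len(word) < 3:
            continue
        taken.add(word)
        out.append(word)
    return out


def _inflect(word: str, pos_tag: str) -> tuple[str, str] | None:
    if pos_tag == "NN":
        return word + "s", "NNS"
    if pos_tag == "VB":
        return word + "ing", "VBG"
    return None


def build_default_lexicon() -> Lexicon:
    """Construct the versioned default lexicon (deterministic)."""
    rng = np.random.default_rng(_LEXICON_SEED)
    pos: dict[str, str] = {}
    lemma: dict[str, str] = {}
    topic: dict[str, str] = {}
    topics: dict[str, list[str]] = {}

    for words, tag in ((_DETERMINERS, "DT"), (_PRONOUNS, "PRP"),
                       (_PREPOSITIONS, "IN"), (_CONJUNCTIONS, "CC"),
                       (_AUXILIARIES, "MD"), (_ADVERBS, "RB"),
                       (_FILLERS, "UH")):
        for w in words:
            pos[w] = tag
            lemma[w] = _IRREGULAR_LEMMAS.get(w, w)
    for w, t in _IRREGULAR_POS.items():
        pos.setdefault(w, t)
        lemma.setdefault(w, _IRREGULAR_LEMMAS.get(w, w))

    taken = set(pos) | set(CONCEPTS) | set(_IRREGULAR_LEMMAS)

    def add_topic(name: str, head: str | None, n_words: int) -> None:
        members: list[str] = []
        if head is not None:
            pos[head] = _CONCEPT_POS.get(head, "NN")
            lemma[head] = head
            topic[head] = name
            members.append(head)
        for i, w in enumerate(_pseudo_words(rng, n_words, taken)):
            tag = _POS_CYCLE[i % len(_POS_CYCLE)]
            pos[w], lemma[w], topic[w] = tag, w, name
            members.append(w)
            if i % 2 == 0:
                inf = _inflect(w, tag)
                if inf is not None and inf[0] not in taken:
                    taken.add(inf[0])
                    pos[inf[0]], lemma[inf[0]], topic[inf[0]] = inf[1], w, name
                    members.append(inf[0])
        topics[name] = members

    for concept in CONCEPTS:
        add_topic(f"c_{concept}", concept, _WORDS_PER_CONCEPT_TOPIC)
    for b in range(N_BACKGROUND_TOPICS):
        add_topic(f"bg_{b:02d}", None, _WORDS_PER_BACKGROUND_TOPIC)

    lex = Lexicon(pos=pos, lemma=lemma, topic=topic, topics=topics)
    lex._finalize_weights()
    return lex


_DEFAULT: Lexicon | None = None


def default_lexicon() -> Lexicon:
    """Cached singleton of the default lexicon."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_default_lexicon()
    return _DEFAULT
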