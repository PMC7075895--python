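"""Latent semantic analysis: concept-proximity scoring of transcripts.

A term-document count matrix over a background corpus is weighted with the
log-entropy scheme and factored by truncated SVD.  Each word's embedding is
its left-singular row scaled by the singular values; proximity between two
words is the cosine of their embeddings.  A transcript's semantic feature
for a concept is the median proximity between the concept word and the
transcript's in-vocabulary lemmas, yielding one feature per concept
(21 with the default concept set).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .lexicon import CONCEPTS
from .text import CleanTranscript

log = logging.getLogger(__name__)


@dataclass
class SemanticModel:
    vocabulary: dict[str, int]          # word -> row index
    vectors: np.ndarray                 # (|V|, k)
    rank: int
    weighting: str
    corpus_fingerprint: str
    _unit: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(self.vectors):
            raise ValueError("one embedding row per vocabulary word required")
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        self._unit = self.vectors / np.maximum(norms, 1e-12)

    def __contains__(self, word: str) -> bool:
        return word in self.vocabulary

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocabulary[word]]


def build_semantic_model(documents: list[list[str]], rank: int = 100,
                         weighting: str = "log_entropy",
                         concepts: tuple[str, ...] | None = CONCEPTS
                         ) -> SemanticModel:
    """Fit the LSA embedding on tokenized documents.

    The sign of each singular vector is fixed by forcing its
    largest-magnitude entry positive, so repeated builds are identical.
    Raises if any requested concept word is missing from the corpus
    vocabulary (pass ``concepts=None`` to skip the check).
    """
    n_docs = len(documents)
    if n_docs < 50:
        raise ValueError("at least 50 documents are required for a stable "
                         f"embedding (got {n_docs})")
    vocab_list = sorted({w for doc in documents for w in doc})
    vocabulary = {w: i for i, w in enumerate(vocab_list)}
    if rank > min(len(vocab_list), n_docs):
        raise ValueError(f"rank {rank} must not exceed "
                         f"min(|V|={len(vocab_list)}, n_docs={n_docs})")

    counts = np.zeros((len(vocab_list), n_docs))
    for j, doc in enumerate(documents):
        for w in doc:
            counts[vocabulary[w], j] += 1.0

    if weighting == "log_entropy":
        row_tot = counts.sum(axis=1, keepdims=True)
        p = np.divide(counts, row_tot, out=np.zeros_like(counts),
                      where=row_tot > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy_weight = 1.0 + plogp.sum(axis=1) / np.log(n_docs)
        X = entropy_weight[:, None] * np.log1p(counts)
    elif weighting == "raw":
        X = counts
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    vectors = U[:, :rank] * S[None, :rank]

    if concepts:
        missing = [c for c in concepts if c not in vocabulary]
        if missing:
            raise ValueError("concept words missing from corpus vocabulary: "
                             + ", ".join(sorted(missing)))
    fingerprint = hashlib.sha256(counts.tobytes()).hexdigest()[:16]
    return SemanticModel(vocabulary=vocabulary, vectors=vectors, rank=rank,
                         weighting=weighting, corpus_fingerprint=fingerprint)


def proximity(model: SemanticModel, word_a: str, word_b: str) -> float:
    """Cosine proximity between two in-vocabulary words, in [-1, 1]."""
    ua = model._unit[model.vocabulary[word_a]]
    ub = model._unit[model.vocabulary[word_b]]
    return float(np.clip(ua @ ub, -1.0, 1.0))


_PROX_CACHE: dict[tuple[int, tuple[str, ...]], np.ndarray] = {}


def concept_proximity_matrix(model: SemanticModel,
                             concepts: tuple[str, ...] = CONCEPTS
                             ) -> np.ndarray:
    """(|V|, n_concepts) cosine table, cached per model/concept set."""
    key = (id(model), tuple(concepts))
    if key not in _PROX_CACHE:
        rows = np.array([model.vocabulary[c] for c in concepts])
        _PROX_CACHE[key] = np.clip(model._unit @ model._unit[rows].T, -1, 1)
    return _PROX_CACHE[key]


def extract_semantic(transcript: CleanTranscript, model: SemanticModel,
                     concepts: tuple[str, ...] = CONCEPTS) -> dict[str, float]:
    """Median concept proximity over the transcript's eligible lemmas.

    Eligible words are all in-vocabulary lemmas (token occurrences count
    with multiplicity).  If no lemma is in vocabulary all features are
    missing (NaN) and a log entry is made.
    """
    table = concept_proximity_matrix(model, tuple(concepts))
    rows = [model.vocabulary[le] for le in transcript.lemmas
            if le in model.vocabulary]
    if not rows:
        log.warning("no in-vocabulary lemmas: semantic features missing")
        return {c: np.nan for c in concepts}
    sub = table[np.asarray(rows)]
    med = np.median(sub, axis=0)
    return {c: float(m) for c, m in zip(concepts, med)}
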