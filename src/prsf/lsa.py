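"""Latent semantic analysis of a retelling corpus.

The corpus (one text condition at a time — the action-text and
non-action-text corpora have separate vocabularies) is represented as a
bag-of-words document-term matrix of raw counts. Plain truncated SVD of the
counts — no centering, no tf-idf — yields an encoding matrix (documents ×
topics) and a dictionary matrix (words × topics); rows of the dictionary
matrix, scaled by the singular values, are the word vectors used downstream.
The number of retained topics k is the smallest that accumulates the
configured share (default 95%) of explained variance, where the
explained-variance ratio of component j is sigma_j^2 / sum(sigma^2).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .preprocess import ProcessedDocument

logger = logging.getLogger(__name__)

#: slack for "cumulative variance >= threshold" comparisons, so a ratio that
#: equals the threshold up to floating-point rounding counts as reaching it
_EPS = 1e-12


class OOVError(KeyError):
    """Raised when a word has no vector (distinct from a zero vector)."""


@dataclass
class DocumentTermMatrix:
    """Bag-of-words counts: m documents x v vocabulary words."""

    counts: np.ndarray  # (m, v) non-negative ints
    vocabulary: list[str]
    doc_ids: list[tuple[str, str]]  # (participant_id, condition)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def build_dtm(processed_docs: list[ProcessedDocument]) -> DocumentTermMatrix:
    """Count lemma frequencies per document over the corpus vocabulary.

    The vocabulary is the sorted set of unique lemmas across the corpus;
    row i sums to the lemma count of document i. A corpus whose documents
    are all empty has no vocabulary and is a hard error.
    """
    if not processed_docs:
        raise ValueError("cannot build a document-term matrix from zero documents")
    vocabulary = sorted({lemma for d in processed_docs for lemma in d.lemmas})
    if not vocabulary:
        raise ValueError("all documents are empty after preprocessing")
    index = {w: j for j, w in enumerate(vocabulary)}
    counts = np.zeros((len(processed_docs), len(vocabulary)), dtype=np.int64)
    for i, doc in enumerate(processed_docs):
        for lemma, c in Counter(doc.lemmas).items():
            counts[i, index[lemma]] = c
    return DocumentTermMatrix(
        counts=counts,
        vocabulary=vocabulary,
        doc_ids=[(d.participant_id, d.condition) for d in processed_docs],
    )


@dataclass
class LSAModel:
    """Truncated SVD of a document-term matrix.

    ``encoding`` is U_k * diag(s_k) (documents x k), ``dictionary`` is
    V_k * diag(s_k) (words x k); both sides carry the singular values, the
    standard LSA term-space convention, held fixed because cosine
    similarities between word vectors are not invariant to per-side
    rescaling.
    """

    encoding: np.ndarray
    dictionary: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    variance_threshold: float
    vocabulary: list[str]
    doc_ids: list[tuple[str, str]]
    _word_index: dict[str, int]


def select_k(explained_variance_ratio: np.ndarray, variance_threshold: float) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    cum = np.cumsum(explained_variance_ratio)
    reached = np.nonzero(cum >= variance_threshold - _EPS)[0]
    if reached.size == 0:
        # numerical rank exhausted before the threshold; use all of it
        k = int(np.count_nonzero(explained_variance_ratio > _EPS))
        logger.warning(
            "variance threshold %.3f unreachable (cumulative max %.6f); "
            "using full numerical rank k=%d",
            variance_threshold,
            cum[-1] if cum.size else 0.0,
            k,
        )
        return max(k, 1)
    return int(reached[0]) + 1


def fit_lsa(dtm: DocumentTermMatrix, variance_threshold: float = 0.95) -> LSAModel:
    """SVD of the raw count matrix, truncated at the variance threshold."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    X = dtm.counts.astype(float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("document-term matrix is all zeros")
    ratios = s**2 / total
    # SVD sign ambiguity: orient each component so its largest-magnitude
    # dictionary entry is positive
    for j in range(s.size):
        col = Vt[j, :]
        if col[np.argmax(np.abs(col))] < 0:
            Vt[j, :] = -col
            U[:, j] = -U[:, j]
    k = select_k(ratios, variance_threshold)
    return LSAModel(
        encoding=U[:, :k] * s[:k],
        dictionary=Vt[:k, :].T * s[:k],
        singular_values=s,
        explained_variance_ratio=ratios,
        k=k,
        variance_threshold=variance_threshold,
        vocabulary=list(dtm.vocabulary),
        doc_ids=list(dtm.doc_ids),
        _word_index={w: j for j, w in enumerate(dtm.vocabulary)},
    )


def word_vector(model: LSAModel, word: str) -> np.ndarray:
    """The word's row of the dictionary matrix (length k).

    Out-of-vocabulary words raise :class:`OOVError` — callers choose the
    fallback; a zero vector would be indistinguishable from a word that
    genuinely has no weight on any topic.
    """
    try:
        j = model._word_index[word]
    except KeyError:
        raise OOVError(word) from None
    return model.dictionary[j]
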