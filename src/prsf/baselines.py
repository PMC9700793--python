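"""Word-embedding benchmark features.

Two feature sets the P-RSF metric is compared against, both computed from a
pre-trained embedding table (e.g. Spanish GloVe) rather than the corpus-fit
LSA space:

- verb-to-verb distance: per retelling, the mean cosine distance of its verb
  tokens to each original-story verb (length n);
- overall semantic structure: the mean embedding of all the retelling's
  preprocessed words (length d).

Out-of-vocabulary words are skipped (not zero-filled — zero vectors distort
cosine distances) and counted; a document with no usable word yields no
feature and is excluded by callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import WordEmbeddingTable
from .metric import _cosine_rows

logger = logging.getLogger(__name__)


@dataclass
class BaselineFeature:
    """One document's feature vector plus its OOV bookkeeping."""

    values: np.ndarray
    n_used: int
    n_oov_skipped: int


def verb_distance_features(
    doc_verbs: Sequence[str],
    original_verbs: Sequence[str],
    embeddings: WordEmbeddingTable,
) -> BaselineFeature | None:
    """Mean cosine distance of the retelling's verbs to each original verb.

    feature_j = mean over usable retelling verb tokens t of
    1 - cos_sim(emb(t), emb(original_verb_j)); entries lie in [0, 2].
    Returns ``None`` (missing-feature signal) if no retelling verb has an
    embedding. Original verbs must all be in vocabulary.
    """
    missing_ref = [v for v in original_verbs if v not in embeddings]
    if missing_ref:
        raise KeyError(f"original verbs lack embeddings: {missing_ref}")
    R = np.vstack([embeddings[v] for v in original_verbs])
    used, n_oov = [], 0
    for t in doc_verbs:
        if t in embeddings:
            used.append(embeddings[t])
        else:
            n_oov += 1
    if not used:
        logger.warning("no retelling verb with an embedding; document excluded")
        return None
    dist = 1.0 - _cosine_rows(np.vstack(used), R)  # (n_used, n_ref)
    return BaselineFeature(
        values=dist.mean(axis=0), n_used=len(used), n_oov_skipped=n_oov
    )


def mean_embedding_features(
    doc_lemmas: Sequence[str], embeddings: WordEmbeddingTable
) -> BaselineFeature | None:
    """Component-wise mean embedding over the document's in-vocabulary words."""
    used, n_oov = [], 0
    for w in doc_lemmas:
        if w in embeddings:
            used.append(embeddings[w])
        else:
            n_oov += 1
    if not used:
        logger.warning("no in-vocabulary word; document excluded")
        return None
    return BaselineFeature(
        values=np.vstack(used).mean(axis=0), n_used=len(used), n_oov_skipped=n_oov
    )
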