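"""The Proximity-to-Reference-Semantic-Field (P-RSF) metric.

P-RSF quantifies how strongly a retelling evokes the semantic field of the
reference story's verbs. For a corpus of m retellings and the n reference
verbs attested in that corpus:

1. *verb importance* w_j — mean cosine similarity between reference verb j's
   LSA vector and the vectors of all words in the corpus vocabulary: the
   weight of verb j's semantic field within the field spanned by the
   retellings;
2. *occurrence matrix* O (m x n) — exact occurrence counts of each reference
   verb per retelling, plus similarity credit: a retelling verb that matches
   no reference verb contributes its cosine similarity (clipped at 0) to its
   nearest reference verb's column;
3. *P-RSF matrix* P = O ∘ w (Hadamard product along columns); a retelling's
   scalar P-RSF score is its row mean. Lower scores mean weaker evocation of
   the target (action or non-action) concepts.

All model fitting (vocabulary, LSA, reference-verb set, importance) happens
on training documents only; :func:`fit_transform_fold` packages that
discipline for cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lsa import DocumentTermMatrix, LSAModel, OOVError, build_dtm, fit_lsa, word_vector
from .preprocess import ProcessedDocument

logger = logging.getLogger(__name__)

#: how a non-reference retelling verb is credited to its nearest reference
#: verb: "similarity" (cosine similarity clipped at 0, the default),
#: "one_minus_distance_raw" (1 - cosine distance, unclipped) or "none"
CREDIT_MODES = ("similarity", "one_minus_distance_raw", "none")


@dataclass(frozen=True)
class ReferenceVerbSet:
    """The original story's verbs attested in the retelling corpus."""

    condition: str
    verbs: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.verbs)


@dataclass
class OccurrenceMatrix:
    """m x n occurrences: exact counts plus similarity credit per cell."""

    O: np.ndarray
    exact: np.ndarray  # integer exact-count part
    credit: np.ndarray  # similarity-credit part, each credited cosine in [0, 1]
    credited_tokens: np.ndarray  # per-document count of credited verb tokens
    oov_tokens: np.ndarray  # per-document count of verb tokens with no vector

    @property
    def n_oov(self) -> int:
        return int(self.oov_tokens.sum())


@dataclass
class PRSFMatrix:
    """P = O ∘ w and the per-document scalar scores (row means)."""

    P: np.ndarray
    score: np.ndarray
    ref_verbs: ReferenceVerbSet
    importance: np.ndarray


def select_reference_verbs(
    original_story_verbs: list[str], corpus_vocabulary: list[str] | set[str], condition: str
) -> ReferenceVerbSet:
    """Original-story verbs that also appear in the corpus vocabulary.

    Original-story order is preserved and duplicates dropped. An empty
    intersection leaves the metric undefined and is a hard error.
    """
    vocab = set(corpus_vocabulary)
    seen: set[str] = set()
    kept = []
    for v in original_story_verbs:
        if v in vocab and v not in seen:
            kept.append(v)
            seen.add(v)
    if not kept:
        raise ValueError(
            f"no {condition} original-story verb is attested in the corpus; "
            "P-RSF is undefined"
        )
    return ReferenceVerbSet(condition=condition, verbs=tuple(kept))


def _cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of A and rows of B.

    Zero-norm rows yield similarity 0 (not NaN) by convention.
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (A @ B.T) / np.outer(na, nb)
    sim[~np.isfinite(sim)] = 0.0
    return sim


def verb_importance(model: LSAModel, ref_verbs: ReferenceVerbSet) -> np.ndarray:
    """w_j = mean cosine similarity of reference verb j to every vocabulary word."""
    V = model.dictionary  # (v, k) — all vocabulary vectors
    R = np.vstack([word_vector(model, v) for v in ref_verbs.verbs])
    sims = _cosine_rows(R, V)  # (n, v)
    n_zero = int(np.sum(np.linalg.norm(V, axis=1) == 0))
    if n_zero:
        logger.warning("%d zero-norm word vectors contribute similarity 0", n_zero)
    return sims.mean(axis=1)


def occurrence_matrix(
    docs_verbs: list[tuple[str, ...]] | list[list[str]],
    ref_verbs: ReferenceVerbSet,
    model: LSAModel,
    credit_mode: str = "similarity",
) -> OccurrenceMatrix:
    """Count reference verbs per document, crediting near-synonyms.

    Exact matches increment the verb's own column. Every non-reference verb
    *token* (duplicates credit repeatedly, mirroring frequency semantics) is
    assigned to the reference verb with the highest cosine similarity (ties:
    lowest index, i.e. original-story order) and contributes credit per
    ``credit_mode``. Tokens without an LSA vector contribute nothing.
    """
    if credit_mode not in CREDIT_MODES:
        raise ValueError(f"credit_mode must be one of {CREDIT_MODES}")
    n = len(ref_verbs)
    m = len(docs_verbs)
    ref_index = {v: j for j, v in enumerate(ref_verbs.verbs)}
    R = np.vstack([word_vector(model, v) for v in ref_verbs.verbs])
    exact = np.zeros((m, n))
    credit = np.zeros((m, n))
    credited_tokens = np.zeros(m, dtype=np.int64)
    oov_tokens = np.zeros(m, dtype=np.int64)
    for i, verbs in enumerate(docs_verbs):
        for token in verbs:
            j = ref_index.get(token)
            if j is not None:
                exact[i, j] += 1
                continue
            if credit_mode == "none":
                continue
            try:
                vec = word_vector(model, token)
            except OOVError:
                oov_tokens[i] += 1
                logger.debug("verb %r has no vector; no credit", token)
                continue
            sims = _cosine_rows(vec[None, :], R)[0]
            j_star = int(np.argmax(sims))  # argmax takes the lowest index on ties
            c = sims[j_star] if credit_mode == "one_minus_distance_raw" else max(0.0, sims[j_star])
            credit[i, j_star] += c
            credited_tokens[i] += 1
    return OccurrenceMatrix(
        O=exact + credit,
        exact=exact,
        credit=credit,
        credited_tokens=credited_tokens,
        oov_tokens=oov_tokens,
    )


def prsf_scores(
    O: OccurrenceMatrix | np.ndarray,
    importance: np.ndarray,
    ref_verbs: ReferenceVerbSet | None = None,
) -> PRSFMatrix:
    """Hadamard product of occurrences and importance; row means as scores.

    The row *mean* (not sum) keeps scores comparable across folds whose
    attested reference-verb counts n differ.
    """
    occ = O.O if isinstance(O, OccurrenceMatrix) else np.asarray(O, dtype=float)
    w = np.asarray(importance, dtype=float)
    if occ.ndim != 2 or occ.shape[1] != w.shape[0]:
        raise ValueError(
            f"shape mismatch: occurrences {occ.shape} vs importance {w.shape}"
        )
    P = occ * w  # broadcasts w across rows: P[i, j] = O[i, j] * w_j
    return PRSFMatrix(
        P=P,
        score=P.mean(axis=1),
        ref_verbs=ref_verbs
        if ref_verbs is not None
        else ReferenceVerbSet("AT", tuple(f"v{j}" for j in range(w.size))),
        importance=w,
    )


@dataclass
class FoldFeatures:
    """Train-fitted P-RSF machinery applied to train and test documents."""

    model: LSAModel
    ref_verbs: ReferenceVerbSet
    importance: np.ndarray
    train: PRSFMatrix
    test: PRSFMatrix
    train_occurrence: OccurrenceMatrix
    test_occurrence: OccurrenceMatrix


def fit_transform_fold(
    train_docs: list[ProcessedDocument],
    test_docs: list[ProcessedDocument],
    original_story_verbs: list[str],
    condition: str,
    variance_threshold: float = 0.95,
    credit_mode: str = "similarity",
) -> FoldFeatures:
    """Fit vocabulary/LSA/reference verbs/importance on training documents
    only, then score both training and held-out documents with them.

    Test verbs absent from the training vocabulary are out-of-vocabulary:
    they earn no credit (and are logged), so held-out documents can never
    influence the fitted semantic space.
    """
    if not train_docs:
        raise ValueError("empty training corpus")
    train_ids = {d.participant_id for d in train_docs}
    if train_ids & {d.participant_id for d in test_docs}:
        raise ValueError("train and test folds share participants")
    dtm = build_dtm(list(train_docs))
    model = fit_lsa(dtm, variance_threshold=variance_threshold)
    ref = select_reference_verbs(original_story_verbs, model.vocabulary, condition)
    w = verb_importance(model, ref)
    occ_train = occurrence_matrix([d.verbs for d in train_docs], ref, model, credit_mode)
    occ_test = occurrence_matrix([d.verbs for d in test_docs], ref, model, credit_mode)
    return FoldFeatures(
        model=model,
        ref_verbs=ref,
        importance=w,
        train=prsf_scores(occ_train, w, ref),
        test=prsf_scores(occ_test, w, ref),
        train_occurrence=occ_train,
        test_occurrence=occ_test,
    )
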