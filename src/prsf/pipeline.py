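"""End-to-end orchestration: corpus -> features -> stats/classification.

Thin compositions of the other modules, shared by the command-line interface
and by scripted analyses. Two fitting regimes exist:

- *descriptive* (:func:`score_corpus`): vocabulary/LSA/importance fitted on
  the whole corpus of one text condition — for group comparisons (ANCOVA)
  and exploratory correlations;
- *predictive* (:func:`prsf_feature_fn`): everything refitted inside each
  training fold — for nested-CV classification, where held-out participants
  must not shape the semantic space.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, metric, stats
from .corpus_io import ParticipantRecord, Transcript
from .lsa import build_dtm, fit_lsa
from .preprocess import LinguisticBackend, ProcessedDocument, process_transcript

logger = logging.getLogger(__name__)

TANDEMS: dict[str, tuple[str, ...]] = {
    # comparison group first, patient (positive) group(s) last
    "all_pd_vs_hc": ("HC", "PD-nMCI", "PD-MCI"),
    "nmci_vs_hc": ("HC", "PD-nMCI"),
    "mci_vs_hc": ("HC", "PD-MCI"),
    "nmci_vs_mci": ("PD-nMCI", "PD-MCI"),
}


def process_corpus(
    transcripts: Sequence[Transcript], backend: LinguisticBackend
) -> dict[str, list[ProcessedDocument]]:
    """Normalize + tag every transcript, grouped by text condition."""
    by_cond: dict[str, list[ProcessedDocument]] = {"AT": [], "nAT": []}
    for t in transcripts:
        by_cond[t.condition].append(process_transcript(t, backend))
    return by_cond


def score_corpus(
    docs_by_condition: dict[str, list[ProcessedDocument]],
    story_verbs: dict[str, list[str]],
    variance_threshold: float = 0.95,
    credit_mode: str = "similarity",
) -> pd.DataFrame:
    """Whole-corpus P-RSF scores, one row per (participant, condition)."""
    rows = []
    for cond, docs in docs_by_condition.items():
        if not docs:
            continue
        model = fit_lsa(build_dtm(docs), variance_threshold=variance_threshold)
        ref = metric.select_reference_verbs(story_verbs[cond], model.vocabulary, cond)
        w = metric.verb_importance(model, ref)
        occ = metric.occurrence_matrix([d.verbs for d in docs], ref, model, credit_mode)
        scores = metric.prsf_scores(occ, w, ref)
        for i, doc in enumerate(docs):
            rows.append(
                {
                    "participant_id": doc.participant_id,
                    "condition": cond,
                    "prsf_score": scores.score[i],
                    "n_reference_verbs": len(ref),
                    "n_exact": int(occ.exact[i].sum()),
                    "n_credited": int(occ.credited_tokens[i]),
                    "n_oov": int(occ.oov_tokens[i]),
                }
            )
    return pd.DataFrame(rows)


def prsf_feature_fn(
    docs: Sequence[ProcessedDocument],
    story_verbs: list[str],
    condition: str,
    variance_threshold: float = 0.95,
    credit_mode: str = "similarity",
) -> classify.FeatureFn:
    """Fold-aware feature extractor over one condition's documents.

    Returns a closure mapping (train_ids, test_ids) to the train-fitted
    P-RSF feature matrices (documents x attested reference verbs).
    """
    by_id = {d.participant_id: d for d in docs if d.condition == condition}

    def feature_fn(train_ids: Sequence[str], test_ids: Sequence[str]):
        train_docs = [by_id[p] for p in train_ids]
        test_docs = [by_id[p] for p in test_ids]
        fold = metric.fit_transform_fold(
            train_docs,
            test_docs,
            story_verbs,
            condition,
            variance_threshold=variance_threshold,
            credit_mode=credit_mode,
        )
        return fold.train.P, fold.test.P

    return feature_fn


def tandem_labels(
    records: Sequence[ParticipantRecord], tandem: str
) -> dict[str, int]:
    """participant -> 0 (comparison class) / 1 (patient class) for a tandem."""
    if tandem not in TANDEMS:
        raise ValueError(f"unknown tandem {tandem!r}; options: {sorted(TANDEMS)}")
    groups = TANDEMS[tandem]
    negative = groups[0]
    return {
        r.participant_id: 0 if r.group == negative else 1
        for r in records
        if r.group in groups
    }


def classify_tandem(
    docs_by_condition: dict[str, list[ProcessedDocument]],
    records: Sequence[ParticipantRecord],
    story_verbs: dict[str, list[str]],
    tandem: str,
    condition: str,
    seed: int = 0,
    search_budget: int = 50,
    variance_threshold: float = 0.95,
    credit_mode: str = "similarity",
) -> classify.ClassificationReport:
    """Nested-CV SVM classification of one tandem on one text condition."""
    labels = tandem_labels(records, tandem)
    docs = [d for d in docs_by_condition[condition] if d.participant_id in labels]
    ids = [d.participant_id for d in docs]
    plan = classify.make_cv_plan(ids, labels, seed=seed)
    fn = prsf_feature_fn(
        docs, story_verbs[condition], condition, variance_threshold, credit_mode
    )
    return classify.nested_cv(fn, labels, plan, search_budget=search_budget)


def ancova_tandem(
    features: pd.DataFrame,
    records: Sequence[ParticipantRecord],
    tandem: str,
    condition: str,
) -> stats.AncovaResult:
    """One-way ANCOVA on P-RSF scores for a tandem and condition, covarying
    for MoCA and IFS."""
    groups = TANDEMS[tandem]
    meta = {r.participant_id: r for r in records if r.group in groups}
    sub = features[
        (features.condition == condition) & features.participant_id.isin(meta)
    ]
    y = sub.prsf_score.to_numpy()
    negative = groups[0]
    labels = [
        "comparison" if meta[p].group == negative else "patient"
        for p in sub.participant_id
    ]
    cov = np.column_stack(
        [
            [meta[p].moca for p in sub.participant_id],
            [meta[p].ifs for p in sub.participant_id],
        ]
    )
    return stats.ancova_one_way(y, labels, cov, covariate_names=["moca", "ifs"])


def correlate_with_updrs(
    features: pd.DataFrame,
    records: Sequence[ParticipantRecord],
    group: str,
    condition: str,
) -> stats.CorrelationResult:
    """Exploratory correlation of P-RSF scores with UPDRS-III in one group."""
    meta = {r.participant_id: r for r in records if r.group == group}
    sub = features[
        (features.condition == condition) & features.participant_id.isin(meta)
    ]
    x = sub.prsf_score.to_numpy()
    y = np.asarray([meta[p].updrs3 for p in sub.participant_id])
    return stats.correlate(x, y)
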