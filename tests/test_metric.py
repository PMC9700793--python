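"""P-RSF metric: reference verbs, importance, occurrences, scores, folds."""

import numpy as np
import pytest

from prsf.lsa import LSAModel, build_dtm, fit_lsa
from prsf.metric import (
    ReferenceVerbSet,
    fit_transform_fold,
    occurrence_matrix,
    prsf_scores,
    select_reference_verbs,
    verb_importance,
)
from prsf.preprocess import ProcessedDocument
from prsf.synthetic import SimConfig, generate_study
from prsf import pipeline


def model_from_vectors(vocab, vectors):
    """LSAModel stub with hand-set dictionary rows (for exact arithmetic)."""
    V = np.asarray(vectors, dtype=float)
    return LSAModel(
        encoding=np.zeros((1, V.shape[1])),
        dictionary=V,
        singular_values=np.ones(V.shape[1]),
        explained_variance_ratio=np.ones(V.shape[1]) / V.shape[1],
        k=V.shape[1],
        variance_threshold=0.95,
        vocabulary=list(vocab),
        doc_ids=[("p00", "AT")],
        _word_index={w: i for i, w in enumerate(vocab)},
    )


class TestSelectReferenceVerbs:
    def test_ordered_intersection(self):
        ref = select_reference_verbs(["v1", "v2", "v3"], {"v1", "v3", "x"}, "AT")
        assert ref.verbs == ("v1", "v3")

    def test_full_overlap_keeps_story_order(self):
        ref = select_reference_verbs(["b", "a"], {"a", "b"}, "AT")
        assert ref.verbs == ("b", "a")

    def test_duplicates_dropped(self):
        ref = select_reference_verbs(["a", "b", "a"], {"a", "b"}, "AT")
        assert ref.verbs == ("a", "b")

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            select_reference_verbs(["v1"], {"x"}, "AT")

    def test_unattested_verb_shrinks_set(self):
        """A fold whose corpus lacks one story verb yields n-1 targets."""
        config = SimConfig(
            n_per_group={"HC": 6},
            retention={("HC", "AT"): 1.0, ("HC", "nAT"): 1.0},
            paraphrase_rate=0.0,
            distractor_rate=0.0,
            seed=3,
        )
        study = generate_study(config)
        docs = pipeline.process_corpus(study.transcripts, study.backend())["AT"]
        vocab = {l for d in docs for l in d.lemmas}
        story = study.story_verbs["AT"] + ["atverbunseen"]
        ref = select_reference_verbs(story, vocab, "AT")
        assert len(ref) == len(story) - 1


class TestVerbImportance:
    def test_self_similarity_alone(self):
        model = model_from_vectors(["v"], [[3.0, 4.0]])
        ref = ReferenceVerbSet("AT", ("v",))
        assert verb_importance(model, ref) == pytest.approx([1.0])

    def test_orthogonal_verb_scores_zero(self):
        model = model_from_vectors(["v", "a", "b"], [[1, 0], [0, 2], [0, -5]])
        ref = ReferenceVerbSet("AT", ("v",))
        # mean over vocab {v, a, b}: cos = 1, 0, 0 -> 1/3
        assert verb_importance(model, ref) == pytest.approx([1 / 3])

    def test_hand_computed_mean_cosine(self):
        vocab = ["u", "v", "x", "y"]
        V = np.array([[1, 0], [0, 1], [1, 1], [1, -1]], dtype=float)
        model = model_from_vectors(vocab, V)
        ref = ReferenceVerbSet("AT", ("u", "v"))
        r2 = 1 / np.sqrt(2)
        expected_u = np.mean([1.0, 0.0, r2, r2])
        expected_v = np.mean([0.0, 1.0, r2, -r2])
        assert verb_importance(model, ref) == pytest.approx([expected_u, expected_v])

    def test_zero_norm_vocab_vector_contributes_zero(self):
        model = model_from_vectors(["v", "z"], [[1, 0], [0, 0]])
        ref = ReferenceVerbSet("AT", ("v",))
        assert verb_importance(model, ref) == pytest.approx([0.5])


class TestOccurrenceMatrix:
    def test_exact_counts_only(self):
        model = model_from_vectors(["a", "b"], [[1, 0], [0, 1]])
        ref = ReferenceVerbSet("AT", ("a", "b"))
        occ = occurrence_matrix([["a", "b"]], ref, model)
        assert occ.O.tolist() == [[1.0, 1.0]]
        assert occ.credit.sum() == 0

    def test_zero_verb_document(self):
        model = model_from_vectors(["a"], [[1.0]])
        ref = ReferenceVerbSet("AT", ("a",))
        occ = occurrence_matrix([[]], ref, model)
        assert occ.O.tolist() == [[0.0]]

    def test_similarity_credit_to_nearest(self):
        # w is at cosine 0.8 to v2 = [0,1] and 0.6 to v1 = [1,0]
        model = model_from_vectors(["v1", "v2", "w"], [[1, 0], [0, 1], [0.6, 0.8]])
        ref = ReferenceVerbSet("AT", ("v1", "v2"))
        occ = occurrence_matrix([["w"]], ref, model)
        np.testing.assert_allclose(occ.O, [[0.0, 0.8]], atol=1e-12)
        assert occ.credited_tokens.tolist() == [1]

    def test_negative_similarity_clipped(self):
        model = model_from_vectors(["v", "w"], [[1, 0], [-1, 0]])
        ref = ReferenceVerbSet("AT", ("v",))
        occ = occurrence_matrix([["w"]], ref, model)
        assert occ.O.tolist() == [[0.0]]
        occ_raw = occurrence_matrix([["w"]], ref, model, credit_mode="one_minus_distance_raw")
        np.testing.assert_allclose(occ_raw.O, [[-1.0]], atol=1e-12)

    def test_oov_token_contributes_nothing(self):
        model = model_from_vectors(["v"], [[1.0]])
        ref = ReferenceVerbSet("AT", ("v",))
        occ = occurrence_matrix([["zzz", "v"]], ref, model)
        assert occ.O.tolist() == [[1.0]]
        assert occ.oov_tokens.tolist() == [1]

    def test_duplicate_tokens_credit_repeatedly(self):
        model = model_from_vectors(["v", "w"], [[1, 0], [0.6, 0.8]])
        ref = ReferenceVerbSet("AT", ("v",))
        occ = occurrence_matrix([["w", "w"]], ref, model)
        np.testing.assert_allclose(occ.O, [[1.2]], atol=1e-12)


class TestPrsfScores:
    def test_zero_row_scores_zero(self):
        res = prsf_scores(np.zeros((1, 3)), np.array([0.5, 0.2, 0.1]))
        assert res.score.tolist() == [0.0]

    def test_arithmetic_identity(self):
        res = prsf_scores(np.array([[1.0, 1.0]]), np.array([0.5, 0.25]))
        assert res.P.tolist() == [[0.5, 0.25]]
        assert res.score == pytest.approx([0.375])

    def test_matches_bruteforce_loop(self, rng):
        O = rng.random((5, 4))
        w = rng.random(4)
        res = prsf_scores(O, w)
        for i in range(5):
            expected = sum(O[i, j] * w[j] for j in range(4)) / 4
            assert res.score[i] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            prsf_scores(np.ones((2, 3)), np.ones(4))

    def test_appending_exact_occurrence_increases_score(self):
        model = model_from_vectors(["a", "b"], [[2, 1], [1, 2]])
        ref = ReferenceVerbSet("AT", ("a", "b"))
        w = verb_importance(model, ref)
        assert (w > 0).all()
        base = prsf_scores(occurrence_matrix([["a"]], ref, model), w).score[0]
        more = prsf_scores(occurrence_matrix([["a", "b"]], ref, model), w).score[0]
        assert more > base

    def test_score_invariant_under_verb_permutation(self):
        model = model_from_vectors(
            ["a", "b", "c"], [[1, 0], [0, 1], [0.6, 0.8]]
        )
        ref = ReferenceVerbSet("AT", ("a", "b"))
        w = verb_importance(model, ref)
        s1 = prsf_scores(occurrence_matrix([["a", "c", "b"]], ref, model), w).score
        s2 = prsf_scores(occurrence_matrix([["b", "a", "c"]], ref, model), w).score
        assert s1 == pytest.approx(s2)


def _fold_docs():
    train = [
        ProcessedDocument(f"t{i}", "AT", ("va", "vb", "x", "y")[: 2 + i % 3], ("va", "vb")[: 1 + i % 2])
        for i in range(6)
    ]
    test = [
        ProcessedDocument("h0", "AT", ("va", "x"), ("va",)),
        ProcessedDocument("h1", "AT", ("zz",), ("zz",)),
    ]
    return train, test


class TestFitTransformFold:
    story = ["va", "vb"]

    def test_test_doc_identical_to_train_doc_gets_identical_feature(self):
        train, _ = _fold_docs()
        twin = ProcessedDocument("h9", "AT", train[0].lemmas, train[0].verbs)
        fold = fit_transform_fold(train, [twin], self.story, "AT")
        assert fold.test.P[0] == pytest.approx(fold.train.P[0])

    def test_all_oov_test_doc_scores_zero(self):
        train, test = _fold_docs()
        fold = fit_transform_fold(train, [test[1]], self.story, "AT")
        assert fold.test.score[0] == 0.0

    def test_participant_overlap_rejected(self):
        train, _ = _fold_docs()
        with pytest.raises(ValueError, match="share"):
            fit_transform_fold(train, [train[0]], self.story, "AT")

    def test_fold_independence_of_train_fit(self):
        """Changing held-out documents never changes the train-fitted
        vocabulary, topic count, reference verbs or importance weights."""
        train, test = _fold_docs()
        f1 = fit_transform_fold(train, [test[0]], self.story, "AT")
        f2 = fit_transform_fold(train, [test[1]], self.story, "AT")
        assert f1.model.vocabulary == f2.model.vocabulary
        assert f1.model.k == f2.model.k
        assert f1.ref_verbs == f2.ref_verbs
        assert np.array_equal(f1.importance, f2.importance)
        assert np.array_equal(f1.model.dictionary, f2.model.dictionary)

    def test_empty_train_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_transform_fold([], [], self.story, "AT")


class TestSyntheticSeparation:
    def test_high_retention_group_scores_higher(self):
        """Retention 0.8 vs 0.5 on the action text: the high-retention group
        has the higher mean P-RSF score in >=95% of replicates."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            config = SimConfig(
                n_per_group={"HC": 40, "PD-nMCI": 40},
                retention={
                    ("HC", "AT"): 0.8,
                    ("HC", "nAT"): 0.8,
                    ("PD-nMCI", "AT"): 0.5,
                    ("PD-nMCI", "nAT"): 0.8,
                },
                seed=2000 + rep,
            )
            study = generate_study(config)
            docs = pipeline.process_corpus(study.transcripts, study.backend())
            feats = pipeline.score_corpus(
                {"AT": docs["AT"]}, study.story_verbs
            )
            by_group = feats.groupby(feats.participant_id.str[:2]).prsf_score.mean()
            wins += by_group["hc"] > by_group["pn"]
        assert wins >= 95
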