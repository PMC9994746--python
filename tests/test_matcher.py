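import numpy as np
import pytest

from preprintmatch.matcher import (
    CandidateScore,
    MatchDecision,
    RuleConfig,
    ablated_config,
    decide,
    match,
    mine_hard_negatives,
    score_candidates,
    train_svm,
)
from preprintmatch.vector_index import candidate_union, cosine_scores, top_k_cosine
from preprintmatch.embeddings import sentence_vector


class StubClassifier:
    """Fixed-output classifier for exercising the rule layer in isolation."""

    def __init__(self, positive: bool):
        self.positive = positive

    def predict(self, score):
        return self.positive


def _cand(pmid="1", title_sim=0.9, abstract_sim=0.9, author_sim=0.5):
    return CandidateScore(pmid=pmid, title_sim=title_sim,
                          abstract_sim=abstract_sim, author_sim=author_sim)


PLAIN = ("plain title one", "alpha beta gamma delta epsilon zeta eta tail")
OTHER = ("other title two", "one two three four five six seven tail")


class TestDecide:
    def test_negative_rescued_by_abstract_prefix(self):
        texts = ("t1", "We present a new method for rapid genome assembly")
        paper = ("t2", "We present a new method for rapid genome annotation")
        d = decide(_cand(), 3, texts, paper, RuleConfig(), StubClassifier(False))
        assert d.accepted and d.path == "rescue_abstract_prefix"

    def test_negative_rescued_by_title_colon(self):
        pre = ("SplicerTool: a tool for splicing", OTHER[1])
        pap = ("SplicerTool: an improved tool", PLAIN[1])
        d = decide(_cand(), 3, pre, pap, RuleConfig(), StubClassifier(False))
        assert d.accepted and d.path == "rescue_title_colon"

    def test_colon_rule_requires_colon_in_both(self):
        pre = ("SplicerTool: a tool", OTHER[1])
        pap = ("SplicerTool a tool", PLAIN[1])
        d = decide(_cand(), 3, pre, pap, RuleConfig(), StubClassifier(False))
        assert not d.accepted

    def test_negative_rescued_by_large_authorset(self):
        d = decide(_cand(author_sim=1.0), 12, PLAIN, OTHER, RuleConfig(),
                   StubClassifier(False))
        assert d.accepted and d.path == "rescue_large_authorset"

    def test_large_authorset_needs_exact_jaccard(self):
        d = decide(_cand(author_sim=0.95), 12, PLAIN, OTHER, RuleConfig(),
                   StubClassifier(False))
        assert not d.accepted and d.path == "svm_negative"

    def test_ten_authors_is_not_enough(self):
        d = decide(_cand(author_sim=1.0), 10, PLAIN, OTHER, RuleConfig(),
                   StubClassifier(False))
        assert not d.accepted

    def test_positive_vetoed_by_low_author_similarity(self):
        d = decide(_cand(title_sim=0.95, abstract_sim=0.95, author_sim=0.2),
                   3, PLAIN, OTHER, RuleConfig(), StubClassifier(True))
        assert not d.accepted and d.path == "vetoed_author_threshold"

    def test_very_high_title_bypasses_author_veto(self):
        d = decide(_cand(title_sim=0.9995, abstract_sim=0.5, author_sim=0.0),
                   3, PLAIN, OTHER, RuleConfig(), StubClassifier(True))
        assert d.accepted and d.path == "svm_positive"

    def test_very_high_abstract_bypasses_author_veto(self):
        d = decide(_cand(title_sim=0.5, abstract_sim=0.9999, author_sim=0.0),
                   3, PLAIN, OTHER, RuleConfig(), StubClassifier(True))
        assert d.accepted and d.path == "svm_positive"

    def test_positive_with_adequate_authors_accepted(self):
        d = decide(_cand(author_sim=0.33), 3, PLAIN, OTHER, RuleConfig(),
                   StubClassifier(True))
        assert d.accepted and d.path == "svm_positive"

    def test_accepted_iff_path_in_accept_set(self):
        with pytest.raises(AssertionError):
            MatchDecision(pmid="1", accepted=True, path="svm_negative",
                          scores=_cand())


class TestTrainSvm:
    def test_separable_features_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        pos = [(0.9 + 0.1 * rng.random(), 0.9 + 0.1 * rng.random(), 1.0)
               for _ in range(30)]
        neg = [(0.1 * rng.random(), 0.1 * rng.random(), 0.0) for _ in range(30)]
        clf = train_svm(pos, neg, seed=0)
        assert all(clf.predict(_cand(title_sim=p[0], abstract_sim=p[1],
                                     author_sim=p[2])) for p in pos)
        assert not any(clf.predict(_cand(title_sim=n[0], abstract_sim=n[1],
                                         author_sim=n[2])) for n in neg)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            train_svm([(1, 1, 1)], [], seed=0)

    def test_permutation_invariant_boundary(self):
        rng = np.random.default_rng(1)
        pos = [tuple(rng.random(3) * 0.3 + 0.7) for _ in range(25)]
        neg = [tuple(rng.random(3) * 0.3) for _ in range(25)]
        clf_a = train_svm(pos, neg, seed=0)
        order = rng.permutation(25)
        clf_b = train_svm([pos[i] for i in order], [neg[i] for i in order], seed=0)
        grid = rng.random((200, 3))
        pred_a = clf_a.svm.predict(grid)
        pred_b = clf_b.svm.predict(grid)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_generative_holdout_accuracy(self, zero_noise_bundle):
        b = zero_noise_bundle
        # hold out a third of each class, train on the rest
        pos, neg = b.positives, b.negatives
        clf = train_svm(pos[: 2 * len(pos) // 3], neg[: 2 * len(neg) // 3], seed=0)
        held = [(p, True) for p in pos[2 * len(pos) // 3:]] + [
            (n, False) for n in neg[2 * len(neg) // 3:]
        ]
        acc = np.mean([clf.predict(s) == label for s, label in held])
        assert acc > 0.9


class TestScoreCandidates:
    def test_self_match_scores_near_one(self, zero_noise_bundle):
        b = zero_noise_bundle
        preprint = b.preprints[0]
        pmid = b.truth[preprint.doi]
        cands = candidate_union([(pmid, 1.0)], [(pmid, 1.0)])
        (score,) = score_candidates(preprint, cands, b.models, b.indices, b.corpus)
        assert score.title_sim == pytest.approx(1.0, abs=1e-4)
        assert score.abstract_sim == pytest.approx(1.0, abs=1e-4)
        assert score.author_sim == 1.0

    def test_unrelated_candidate_scores_lower(self, zero_noise_bundle):
        b = zero_noise_bundle
        preprint = b.preprints[0]
        own = b.truth[preprint.doi]
        other = next(p for p in b.corpus if p != own)
        cands = candidate_union([(other, 0.0)], [(other, 0.0)])
        (score,) = score_candidates(preprint, cands, b.models, b.indices, b.corpus)
        assert score.title_sim < 0.999
        assert score.abstract_sim < 0.999

    def test_missing_abstract_flagged_zero(self, zero_noise_bundle):
        import copy

        b = zero_noise_bundle
        preprint = b.preprints[0]
        pmid = b.truth[preprint.doi]
        corpus = dict(b.corpus)
        stripped = copy.deepcopy(corpus[pmid])
        stripped.abstract = None
        corpus[pmid] = stripped
        cands = candidate_union([(pmid, 1.0)], [])
        (score,) = score_candidates(preprint, cands, b.models, b.indices, corpus)
        assert score.abstract_sim == 0.0
        assert score.abstract_missing

    def test_desync_raises(self, zero_noise_bundle):
        b = zero_noise_bundle
        cands = candidate_union([("999999999", 1.0)], [])
        with pytest.raises(KeyError):
            score_candidates(b.preprints[0], cands, b.models, b.indices, b.corpus)


class TestMineHardNegatives:
    def test_matches_exhaustive_argmax_oracle(self, zero_noise_bundle):
        b = zero_noise_bundle
        unpublished = [p for p in b.preprints if p.announced_pub_id is None][:5]
        mined = mine_hard_negatives(unpublished, b.models, b.indices, b.corpus, n=5)
        ids = np.asarray(b.indices["title"].row_ids)
        for preprint, (doi, score) in zip(unpublished, mined):
            assert doi == preprint.doi
            t = cosine_scores(b.indices["title"],
                              sentence_vector(b.models["title"], preprint.title))
            a = cosine_scores(b.indices["abstract"],
                              sentence_vector(b.models["abstract"], preprint.abstract))
            product = t * a
            best = int(np.lexsort((ids, -product))[0])
            assert score.pmid == str(ids[best])
            assert score.title_sim * score.abstract_sim == pytest.approx(
                float(product[best]), abs=1e-5
            )

    def test_planted_twin_is_emitted(self, zero_noise_bundle):
        b = zero_noise_bundle
        # a preprint WITH a true twin, masquerading as unannounced
        preprint = next(p for p in b.preprints if b.truth[p.doi] is not None)
        unannounced = type(preprint)(
            doi=preprint.doi, title=preprint.title, abstract=preprint.abstract,
            posted_date=preprint.posted_date, authors=preprint.authors,
        )
        ((_, score),) = mine_hard_negatives([unannounced], b.models, b.indices,
                                            b.corpus, n=1)
        assert score.pmid == b.truth[preprint.doi]

    def test_n_zero_empty(self, zero_noise_bundle):
        b = zero_noise_bundle
        assert mine_hard_negatives(b.preprints, b.models, b.indices, b.corpus, n=0) == []


class TestMatch:
    def test_recovers_planted_twin(self, zero_noise_bundle):
        b = zero_noise_bundle
        published = [p for p in b.preprints if b.truth[p.doi] is not None]
        hits = sum(
            match(p, b.corpus, b.models, b.indices, b.classifier, b.config).matched_pmid
            == b.truth[p.doi]
            for p in published[:20]
        )
        assert hits == 20

    def test_unpublished_preprint_gets_no_match(self, zero_noise_bundle):
        b = zero_noise_bundle
        unpublished = [p for p in b.preprints if b.truth[p.doi] is None]
        results = [
            match(p, b.corpus, b.models, b.indices, b.classifier, b.config)
            for p in unpublished[:10]
        ]
        assert all(r.matched_pmid is None for r in results)

    def test_empty_corpus_no_match_empty_trace(self, zero_noise_bundle):
        b = zero_noise_bundle
        result = match(b.preprints[0], {}, b.models, b.indices, b.classifier,
                       b.config)
        assert result.matched_pmid is None
        assert result.decision_trace == []

    def test_match_stays_in_candidate_union(self, zero_noise_bundle):
        b = zero_noise_bundle
        for preprint in b.preprints[:10]:
            q_t = sentence_vector(b.models["title"], preprint.title)
            q_a = sentence_vector(b.models["abstract"], preprint.abstract)
            union = candidate_union(
                top_k_cosine(b.indices["title"], q_t, k=b.config.top_k),
                top_k_cosine(b.indices["abstract"], q_a, k=b.config.top_k),
            )
            result = match(preprint, b.corpus, b.models, b.indices, b.classifier,
                           b.config)
            if result.matched_pmid is not None:
                assert result.matched_pmid in union.pmids

    def test_best_candidate_selected_by_product(self, zero_noise_bundle):
        b = zero_noise_bundle
        preprint = next(p for p in b.preprints if b.truth[p.doi] is not None)
        result = match(preprint, b.corpus, b.models, b.indices, b.classifier,
                       b.config)
        accepted = [d for d in result.decision_trace if d.accepted]
        assert accepted
        best = min(accepted, key=lambda d: (-d.scores.product, d.pmid))
        assert result.matched_pmid == best.pmid


class TestAblatedConfig:
    def test_unknown_strategy_error(self):
        with pytest.raises(ValueError):
            ablated_config("authors-only")

    @pytest.mark.parametrize(
        ("strategy", "flags"),
        [
            ("title", (True, False, False)),
            ("abstract", (False, True, False)),
            ("abstract+title", (True, True, False)),
            ("title+authors", (True, False, True)),
            ("full", (True, True, True)),
        ],
    )
    def test_flag_mapping(self, strategy, flags):
        cfg = ablated_config(strategy)
        assert (cfg.use_title, cfg.use_abstract, cfg.use_authors) == flags

    def test_feature_names_follow_flags(self):
        assert ablated_config("title+authors").feature_names == (
            "title_sim", "author_sim",
        )
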