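"""The decision core: candidate scoring, SVM + rule classification,
hard-negative mining, and per-preprint match selection.

Each candidate paper gets a three-feature score (title cosine, abstract
cosine, author Jaccard). An SVM over those features makes the first
call; a small rule layer then rescues specific SVM false negatives
(identical abstract openings, identical pre-colon titles, exactly
matching large author sets) and vetoes SVM positives whose author
similarity is too low without very high text similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .author_match import author_score
from .embeddings import EmbeddingModel, sentence_vector
from .records import PaperRecord, PreprintRecord
from .vector_index import (
    CandidateSet,
    VectorIndex,
    candidate_union,
    cosine_scores,
    top_k_cosine,
)

logger = logging.getLogger(__name__)

ACCEPT_PATHS = frozenset(
    {"svm_positive", "rescue_abstract_prefix", "rescue_title_colon",
     "rescue_large_authorset"}
)
FEATURE_NAMES = ("title_sim", "abstract_sim", "author_sim")


@dataclass(frozen=True)
class CandidateScore:
    pmid: str
    title_sim: float
    abstract_sim: float
    author_sim: float
    abstract_missing: bool = False

    def features(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=np.float64)

    @property
    def product(self) -> float:
        return self.title_sim * self.abstract_sim


@dataclass(frozen=True)
class MatchDecision:
    pmid: str
    accepted: bool
    path: str
    scores: CandidateScore

    def __post_init__(self) -> None:
        assert self.accepted == (self.path in ACCEPT_PATHS)


@dataclass
class MatchResult:
    preprint_doi: str
    matched_pmid: str | None
    decision_trace: list[MatchDecision] = field(default_factory=list)


@dataclass
class RuleConfig:
    """Thresholds for the rule layer, plus feature-availability gates.

    The ``use_*`` flags support ablations: a rule requiring a disabled
    feature never fires, and the author veto is skipped when authors are
    excluded from the feature set.
    """

    very_high_sim: float = 0.999
    author_veto_min: float = 0.33
    abstract_prefix_words: int = 7
    large_authorset_min: int = 10  # rule fires strictly above this
    top_k: int = 100
    use_title: bool = True
    use_abstract: bool = True
    use_authors: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.very_high_sim <= 1:
            raise ValueError("very_high_sim must be in (0, 1]")
        if not 0 <= self.author_veto_min <= 1:
            raise ValueError("author_veto_min must be in [0, 1]")
        if self.abstract_prefix_words <= 0 or self.large_authorset_min < 0:
            raise ValueError("rule sizes must be positive")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = []
        if self.use_title:
            names.append("title_sim")
        if self.use_abstract:
            names.append("abstract_sim")
        if self.use_authors:
            names.append("author_sim")
        if not names:
            raise ValueError("at least one feature must be enabled")
        return tuple(names)


@dataclass
class MatchClassifier:
    """Trained SVM plus the feature columns it was fit on."""

    svm: SVC
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, score: CandidateScore) -> bool:
        x = score.features(self.feature_names).reshape(1, -1)
        return bool(self.svm.predict(x)[0] == 1)


def train_svm(
    positives: Sequence[CandidateScore | Sequence[float]],
    negatives: Sequence[CandidateScore | Sequence[float]],
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    seed: int = 0,
) -> MatchClassifier:
    """Fit an RBF-kernel SVM (C=1, gamma='scale') on labeled feature rows.

    Deterministic given fixed inputs; training-order permutations do not
    change the decision boundary.
    """
    if not positives or not negatives:
        raise ValueError("training requires both positive and negative pairs")

    def as_row(p) -> np.ndarray:
        if isinstance(p, CandidateScore):
            return p.features(feature_names)
        return np.asarray(p, dtype=np.float64)

    x = np.vstack([as_row(p) for p in positives] + [as_row(n) for n in negatives])
    y = np.array([1] * len(positives) + [0] * len(negatives))
    svm = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    svm.fit(x, y)
    return MatchClassifier(svm=svm, feature_names=feature_names)


def score_candidates(
    preprint: PreprintRecord,
    candidates: CandidateSet,
    models: dict[str, EmbeddingModel],
    indices: dict[str, VectorIndex],
    corpus: dict[str, PaperRecord],
) -> list[CandidateScore]:
    """Compute the 3-feature vector for every candidate, sorted by pmid.

    Preprint vectors are recomputed with the same embedding process used
    for the corpus; paper vectors are the stored index rows. A candidate
    pmid absent from the corpus means the index and corpus are out of
    sync and raises ``KeyError``.
    """
    missing = sorted(p for p in candidates.pmids if p not in corpus)
    if missing:
        raise KeyError(
            f"candidate pmids not in corpus (index/corpus desync): {missing[:5]}"
        )
    q_title = sentence_vector(models["title"], preprint.title)
    q_abstract = sentence_vector(models["abstract"], preprint.abstract)
    scores = []
    for pmid in sorted(candidates.pmids):
        paper = corpus[pmid]
        title_sim = float(np.dot(q_title.values, indices["title"].row_of(pmid)))
        if paper.abstract:
            abstract_sim = float(
                np.dot(q_abstract.values, indices["abstract"].row_of(pmid))
            )
            abstract_missing = False
        else:
            abstract_sim = 0.0
            abstract_missing = True
        feat = author_score(preprint.authors, paper.authors)
        scores.append(
            CandidateScore(
                pmid=pmid,
                title_sim=title_sim,
                abstract_sim=abstract_sim,
                author_sim=feat.score,
                abstract_missing=abstract_missing,
            )
        )
    return scores


def mine_hard_negatives(
    unannounced_preprints: Sequence[PreprintRecord],
    models: dict[str, EmbeddingModel],
    indices: dict[str, VectorIndex],
    corpus: dict[str, PaperRecord],
    n: int | None = None,
) -> list[tuple[str, CandidateScore]]:
    """For preprints without an announced publication, emit the paper with
    the highest title×abstract similarity product for external curation.

    The argmax is exhaustive over the whole corpus (ties by ascending
    pmid). Returns ``(preprint_doi, CandidateScore)`` pairs.
    """
    out: list[tuple[str, CandidateScore]] = []
    pool = [p for p in unannounced_preprints if p.announced_pub_id is None]
    if n is not None:
        pool = pool[:n]
    title_index = indices["title"]
    abstract_index = indices["abstract"]
    ids = np.asarray(title_index.row_ids)
    for preprint in pool:
        t_sims = cosine_scores(title_index, sentence_vector(models["title"], preprint.title))
        a_sims = cosine_scores(
            abstract_index, sentence_vector(models["abstract"], preprint.abstract)
        )
        product = t_sims * a_sims
        best = int(np.lexsort((ids, -product))[0])
        pmid = str(ids[best])
        feat = author_score(preprint.authors, corpus[pmid].authors)
        out.append(
            (
                preprint.doi,
                CandidateScore(
                    pmid=pmid,
                    title_sim=float(t_sims[best]),
                    abstract_sim=float(a_sims[best]),
                    author_sim=feat.score,
                ),
            )
        )
    return out


def _abstract_prefix_equal(a: str | None, b: str | None, n_words: int) -> bool:
    if not a or not b:
        return False
    ta, tb = a.strip().split(), b.strip().split()
    if len(ta) < n_words or len(tb) < n_words:
        return False
    return ta[:n_words] == tb[:n_words]


def _title_colon_equal(a: str | None, b: str | None) -> bool:
    if not a or not b or ":" not in a or ":" not in b:
        return False
    pa, pb = a.split(":", 1)[0].strip(), b.split(":", 1)[0].strip()
    return bool(pa) and pa == pb


def decide(
    candidate: CandidateScore,
    preprint_author_count: int,
    preprint_texts: tuple[str | None, str | None],
    paper_texts: tuple[str | None, str | None],
    config: RuleConfig,
    classifier: MatchClassifier,
) -> MatchDecision:
    """Apply the SVM and the rule layer to one candidate; pure function.

    ``preprint_texts`` / ``paper_texts`` are ``(title, abstract)`` pairs
    of the raw strings, needed for the exact prefix/colon checks.
    """
    pre_title, pre_abstract = preprint_texts
    pap_title, pap_abstract = paper_texts
    positive = classifier.predict(candidate)

    if not positive:
        if config.use_abstract and _abstract_prefix_equal(
            pre_abstract, pap_abstract, config.abstract_prefix_words
        ):
            return MatchDecision(candidate.pmid, True, "rescue_abstract_prefix", candidate)
        if config.use_title and _title_colon_equal(pre_title, pap_title):
            return MatchDecision(candidate.pmid, True, "rescue_title_colon", candidate)
        if (
            config.use_authors
            and preprint_author_count > config.large_authorset_min
            and candidate.author_sim == 1.0
        ):
            return MatchDecision(candidate.pmid, True, "rescue_large_authorset", candidate)
        return MatchDecision(candidate.pmid, False, "svm_negative", candidate)

    very_high = (config.use_title and candidate.title_sim > config.very_high_sim) or (
        config.use_abstract and candidate.abstract_sim > config.very_high_sim
    )
    if not very_high and config.use_authors and candidate.author_sim < config.author_veto_min:
        return MatchDecision(candidate.pmid, False, "vetoed_author_threshold", candidate)
    return MatchDecision(candidate.pmid, True, "svm_positive", candidate)


def match(
    preprint: PreprintRecord,
    corpus: dict[str, PaperRecord],
    models: dict[str, EmbeddingModel],
    indices: dict[str, VectorIndex],
    classifier: MatchClassifier,
    config: RuleConfig | None = None,
) -> MatchResult:
    """Retrieve, score and decide; return the best accepted match or none.

    Among accepted candidates the one with the highest title×abstract
    similarity product wins, ties broken by ascending pmid.
    """
    config = config or RuleConfig()
    if not corpus:
        return MatchResult(preprint_doi=preprint.doi, matched_pmid=None)
    if models is None or indices is None or classifier is None:
        raise ValueError("matcher requires trained models, indices and classifier")

    q_title = sentence_vector(models["title"], preprint.title)
    q_abstract = sentence_vector(models["abstract"], preprint.abstract)
    title_topk = top_k_cosine(indices["title"], q_title, k=config.top_k)
    abstract_topk = top_k_cosine(indices["abstract"], q_abstract, k=config.top_k)
    candidates = candidate_union(title_topk, abstract_topk)

    scores = score_candidates(preprint, candidates, models, indices, corpus)
    trace = []
    for cand in scores:
        paper = corpus[cand.pmid]
        trace.append(
            decide(
                cand,
                len(preprint.authors),
                (preprint.title, preprint.abstract),
                (paper.title, paper.abstract),
                config,
                classifier,
            )
        )
    accepted = [d for d in trace if d.accepted]
    if not accepted:
        return MatchResult(preprint.doi, None, trace)
    best = min(accepted, key=lambda d: (-d.scores.product, d.pmid))
    return MatchResult(preprint.doi, best.pmid, trace)


def ablated_config(strategy: str, base: RuleConfig | None = None) -> RuleConfig:
    """RuleConfig for a named feature-subset strategy."""
    base = base or RuleConfig()
    flags = {
        "title": (True, False, False),
        "abstract": (False, True, False),
        "abstract+title": (True, True, False),
        "title+authors": (True, False, True),
        "full": (True, True, True),
    }
    if strategy not in flags:
        raise ValueError(f"unknown ablation strategy: {strategy!r}")
    t, a, au = flags[strategy]
    return replace(base, use_title=t, use_abstract=a, use_authors=au)
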