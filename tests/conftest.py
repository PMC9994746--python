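"""Shared fixtures: small generated corpora and a trained pipeline bundle.

The expensive bundle (embeddings + indices + classifier over a zero-noise
corpus) is session-scoped so matcher and evaluation tests share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from preprintmatch import embeddings as emb
from preprintmatch.fixtures import (
    FixtureConfig,
    generate_corpus,
    labeled_training_pairs,
)
from preprintmatch.matcher import RuleConfig, train_svm
from preprintmatch.vector_index import build_index


@dataclass
class PipelineBundle:
    preprints: list
    papers: list
    truth: object
    corpus: dict
    models: dict
    indices: dict
    classifier: object
    config: RuleConfig
    positives: list
    negatives: list


def build_bundle(
    fixture_config: FixtureConfig,
    dimension: int = 50,
    n_pos: int = 40,
    n_neg: int = 30,
    top_k: int = 20,
) -> PipelineBundle:
    preprints, papers, truth = generate_corpus(fixture_config)
    corpus = {p.pmid: p for p in papers}
    models, indices = {}, {}
    for kind in ("title", "abstract"):
        texts = [(p.title if kind == "title" else p.abstract) or "" for p in papers]
        models[kind] = emb.train_model(
            texts, kind, dimension=dimension, min_count=1, seed=0
        )
        vectors = [emb.sentence_vector(models[kind], t) for t in texts]
        indices[kind] = build_index(
            vectors, [p.pmid for p in papers], field_kind=kind
        )
    positives, negatives = labeled_training_pairs(
        preprints, truth, models, indices, corpus,
        n_pos=n_pos, n_neg=n_neg, seed=0,
    )
    classifier = train_svm(positives, negatives, seed=0)
    return PipelineBundle(
        preprints=preprints, papers=papers, truth=truth, corpus=corpus,
        models=models, indices=indices, classifier=classifier,
        config=RuleConfig(top_k=top_k),
        positives=positives, negatives=negatives,
    )


@pytest.fixture(scope="session")
def zero_noise_bundle() -> PipelineBundle:
    return build_bundle(
        FixtureConfig(n_pairs=60, n_decoys=80, n_unpublished=40, seed=1)
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small generated corpus without any trained models."""
    return generate_corpus(
        FixtureConfig(n_pairs=20, n_decoys=20, n_unpublished=10, seed=7)
    )
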