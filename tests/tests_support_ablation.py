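"""Helper for the ablation comparison test: a corpus where author fields
carry signal that titles alone cannot provide (frequent fore/last flips
plus title revision)."""

from __future__ import annotations

from preprintmatch.evaluation import ablation_run
from preprintmatch.fixtures import FixtureConfig
from preprintmatch.pipeline import truth_to_labels


def run_flip_heavy_comparison() -> tuple[float, float]:
    from conftest import build_bundle

    bundle = build_bundle(
        FixtureConfig(
            n_pairs=40, n_decoys=50, n_unpublished=20, seed=23,
            text_sub_rate=0.35, author_flip_rate=0.4,
        ),
        n_pos=30, n_neg=15,
    )
    labels = truth_to_labels(bundle.truth)
    rows = {
        strategy: ablation_run(
            strategy, bundle.preprints, labels, bundle.corpus, bundle.models,
            bundle.indices, (bundle.positives, bundle.negatives),
        )
        for strategy in ("title", "full")
    }
    title_f1 = rows["title"]["f1"] or 0.0
    full_f1 = rows["full"]["f1"] or 0.0
    return title_f1, full_f1
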