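"""Evaluation: test-set construction, confusion counts, metrics,
paired-tool comparison, ablations, and matched-pair gap reporting.

The test-set construction follows a consensus flow: preprints matched
by neither the server announcements nor the tool are true negatives;
preprints matched by both to the same paper are true positives; all
other cases are resolved by an externally supplied curation map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    #: positives whose prediction named the wrong paper (reported
    #: separately; counted in fp to keep tp+fp+fn+tn additive)
    wrong_pmid: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiscordantTable:
    a: int  # tool A correct, tool B incorrect
    b: int  # tool B correct, tool A incorrect

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("discordant counts must be nonnegative")


@dataclass(frozen=True)
class TestSetLabel:
    __test__ = False  # not a pytest class, despite the name

    preprint_doi: str
    label: str  # "true_positive" | "true_negative"
    truth_pmid: str | None = None
    source: str = "both_agree"  # "both_agree" | "both_absent" | "curated"

    def __post_init__(self) -> None:
        if self.label == "true_positive" and not self.truth_pmid:
            raise ValueError("true_positive labels require a truth pmid")


@dataclass
class TestSetSummary:
    n_sampled: int
    n_excluded_not_indexed: int
    n_true_positive: int
    n_true_negative: int
    labels: list[TestSetLabel] = field(default_factory=list)


class UnresolvedConflictError(ValueError):
    def __init__(self, dois: list[str]):
        self.dois = dois
        super().__init__(
            f"conflicting matches need curation for: {', '.join(dois[:10])}"
            + ("..." if len(dois) > 10 else "")
        )


def construct_test_set(
    sampled_preprints: Sequence[str],
    announced_matches: Mapping[str, str],
    tool_matches: Mapping[str, str | None],
    curation: Mapping[str, str | None] | None = None,
    indexed: Callable[[str], bool] | None = None,
) -> TestSetSummary:
    """Label sampled preprints via the two-method consensus flow.

    Preprints whose announced paper fails the ``indexed`` predicate are
    excluded entirely. Agreement on a pmid → true positive; absence from
    both methods → true negative; anything else must appear in
    ``curation`` (pmid → positive, None → negative) or the call fails.
    Conservation: excluded + labeled = sampled.
    """
    curation = curation or {}
    indexed = indexed or (lambda pmid: True)
    labels: list[TestSetLabel] = []
    excluded = 0
    unresolved: list[str] = []
    for doi in sampled_preprints:
        announced = announced_matches.get(doi)
        if announced is not None and not indexed(announced):
            excluded += 1
            continue
        tool = tool_matches.get(doi)
        if announced is None and tool is None:
            labels.append(TestSetLabel(doi, "true_negative", source="both_absent"))
        elif announced is not None and tool is not None and announced == tool:
            labels.append(
                TestSetLabel(doi, "true_positive", truth_pmid=announced,
                             source="both_agree")
            )
        else:
            if doi not in curation:
                unresolved.append(doi)
                continue
            resolution = curation[doi]
            if resolution is None:
                labels.append(TestSetLabel(doi, "true_negative", source="curated"))
            else:
                labels.append(
                    TestSetLabel(doi, "true_positive", truth_pmid=resolution,
                                 source="curated")
                )
    if unresolved:
        raise UnresolvedConflictError(unresolved)
    n_pos = sum(1 for l in labels if l.label == "true_positive")
    n_neg = len(labels) - n_pos
    return TestSetSummary(
        n_sampled=len(sampled_preprints),
        n_excluded_not_indexed=excluded,
        n_true_positive=n_pos,
        n_true_negative=n_neg,
        labels=labels,
    )


def confusion_counts(
    predictions: Mapping[str, str | None],
    truth: Sequence[TestSetLabel],
    double_count_wrong_pmid: bool = False,
) -> EvalCounts:
    """Tally TP/FP/FN/TN against the labeled test set.

    A wrong-pmid prediction on a positive counts as FP (the missed
    positive is tracked in ``wrong_pmid``); with
    ``double_count_wrong_pmid`` it counts as FP and FN, breaking
    additivity.
    """
    truth_dois = {l.preprint_doi for l in truth}
    unknown = sorted(set(predictions) - truth_dois)
    if unknown:
        raise KeyError(f"predictions for dois outside the test set: {unknown[:5]}")
    counts = EvalCounts()
    for label in truth:
        if label.preprint_doi not in predictions:
            raise KeyError(f"no prediction for {label.preprint_doi}")
        pred = predictions[label.preprint_doi]
        if label.label == "true_positive":
            if pred is None:
                counts.fn += 1
            elif pred == label.truth_pmid:
                counts.tp += 1
            else:
                counts.fp += 1
                counts.wrong_pmid += 1
                if double_count_wrong_pmid:
                    counts.fn += 1
        else:
            if pred is None:
                counts.tn += 1
            else:
                counts.fp += 1
    return counts


def precision_recall_f1(
    counts: EvalCounts,
) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, F1) as percentages; None when undefined."""
    precision = (
        100.0 * counts.tp / (counts.tp + counts.fp)
        if counts.tp + counts.fp > 0
        else None
    )
    recall = (
        100.0 * counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else None
    )
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 100.0 * 2 * counts.tp / denom if denom > 0 else None
    return precision, recall, f1


def correctness(
    predictions: Mapping[str, str | None], truth: Sequence[TestSetLabel]
) -> dict[str, bool]:
    """Per-preprint correctness: right absence, or the exact truth pmid."""
    out = {}
    for label in truth:
        pred = predictions[label.preprint_doi]
        if label.label == "true_negative":
            out[label.preprint_doi] = pred is None
        else:
            out[label.preprint_doi] = pred == label.truth_pmid
    return out


def discordant_table(
    predictions_a: Mapping[str, str | None],
    predictions_b: Mapping[str, str | None],
    truth: Sequence[TestSetLabel],
) -> DiscordantTable:
    correct_a = correctness(predictions_a, truth)
    correct_b = correctness(predictions_b, truth)
    a = sum(1 for d in correct_a if correct_a[d] and not correct_b[d])
    b = sum(1 for d in correct_a if correct_b[d] and not correct_a[d])
    return DiscordantTable(a=a, b=b)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    exact_pvalue: float
    no_discordance: bool


def mcnemar_test(table: DiscordantTable) -> McNemarResult:
    """Chi-square statistic (a−b)²/(a+b) plus the exact binomial p-value.

    Both are reported: the exact two-sided binomial over a+b trials at
    p=1/2 is the decision value; the chi-square form is the printed
    statistic. a+b = 0 → statistic 0, p = 1, flagged.
    """
    a, b = table.a, table.b
    if a + b == 0:
        return McNemarResult(statistic=0.0, exact_pvalue=1.0, no_discordance=True)
    statistic = (a - b) ** 2 / (a + b)
    pvalue = stats.binomtest(min(a, b), a + b, 0.5, alternative="two-sided").pvalue
    return McNemarResult(statistic=statistic, exact_pvalue=min(1.0, float(pvalue)),
                         no_discordance=False)


ABLATION_STRATEGIES = ("title", "abstract", "abstract+title", "title+authors", "full")


def ablation_run(
    strategy: str,
    test_preprints,
    truth: Sequence[TestSetLabel],
    corpus,
    models,
    indices,
    training_pairs,
    seed: int = 0,
    base_config=None,
) -> dict:
    """Retrain the decision layer on a feature subset and evaluate it.

    ``training_pairs`` is ``(positives, negatives)`` of CandidateScore
    rows; the SVM is refit on the subset's columns and rules requiring
    absent features are disabled. Returns a metric row dict.
    """
    from .matcher import ablated_config, match, train_svm

    if strategy not in ABLATION_STRATEGIES:
        raise ValueError(f"unknown ablation strategy: {strategy!r}")
    config = ablated_config(strategy, base_config)
    positives, negatives = training_pairs
    classifier = train_svm(
        positives, negatives, feature_names=config.feature_names, seed=seed
    )
    predictions = {
        p.doi: match(p, corpus, models, indices, classifier, config).matched_pmid
        for p in test_preprints
    }
    counts = confusion_counts(predictions, truth)
    precision, recall, f1 = precision_recall_f1(counts)
    return {
        "method": strategy,
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "counts": counts,
    }


def ablation_table(strategies, *args, **kwargs) -> list[dict]:
    return [ablation_run(s, *args, **kwargs) for s in strategies]


@dataclass
class PairReport:
    gap_days: np.ndarray
    bin_edges_days: np.ndarray
    histogram: np.ndarray
    bin_index: np.ndarray
    median_abstract_sim: np.ndarray
    mean_title_sim: np.ndarray
    abstract_gap_correlation: float | None
    title_gap_correlation: float | None
    n_negative_gaps: int


def pair_reporting(matches: Sequence[tuple]) -> PairReport:
    """Time-gap histogram and per-bin similarity statistics.

    ``matches`` holds ``(preprint, paper, scores)`` triples with dates
    and a CandidateScore. Gaps are paper date − posted date in days
    (negatives retained and counted); bins are 7-day, left-closed.
    Correlations are Pearson r between bin index and the per-bin
    statistic (median abstract sim, mean title sim).
    """
    gaps = np.array(
        [(paper.pub_date - pre.posted_date).days for pre, paper, _ in matches],
        dtype=np.int64,
    )
    title_sims = np.array([s.title_sim for _, _, s in matches])
    abstract_sims = np.array([s.abstract_sim for _, _, s in matches])
    n_negative = int(np.sum(gaps < 0))

    if gaps.size == 0:
        empty = np.array([])
        return PairReport(gaps, empty, empty, empty, empty, empty, None, None, 0)

    lo = (gaps.min() // 7) * 7
    hi = (gaps.max() // 7 + 1) * 7
    edges = np.arange(lo, hi + 1, 7)
    histogram, _ = np.histogram(gaps, bins=edges)
    which = np.digitize(gaps, edges) - 1

    bin_index, med_abs, mean_tit = [], [], []
    for i in range(len(edges) - 1):
        mask = which == i
        if not mask.any():
            continue
        bin_index.append(i)
        med_abs.append(float(np.median(abstract_sims[mask])))
        mean_tit.append(float(np.mean(title_sims[mask])))
    bin_index = np.asarray(bin_index)
    med_abs = np.asarray(med_abs)
    mean_tit = np.asarray(mean_tit)

    def _corr(y: np.ndarray) -> float | None:
        if len(bin_index) < 2 or np.allclose(y, y[0]):
            return None
        return float(stats.pearsonr(bin_index.astype(float), y).statistic)

    return PairReport(
        gap_days=gaps,
        bin_edges_days=edges,
        histogram=histogram,
        bin_index=bin_index,
        median_abstract_sim=med_abs,
        mean_title_sim=mean_tit,
        abstract_gap_correlation=_corr(med_abs),
        title_gap_correlation=_corr(mean_tit),
        n_negative_gaps=n_negative,
    )
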