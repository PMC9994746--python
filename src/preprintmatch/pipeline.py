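"""Stage orchestration: one working directory, manifests, idempotent reruns.

Each stage reads its inputs from the working directory, writes its
outputs there, and records a manifest (config hash, seed, counts). A
completed deterministic stage whose manifest matches the current config
is skipped unless forced.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import embeddings as emb
from . import fixtures as fx
from . import matcher as mt
from . import preprint_ingest, pubmed_ingest
from .evaluation import (
    TestSetLabel,
    confusion_counts,
    discordant_table,
    mcnemar_test,
    precision_recall_f1,
)
from .vector_index import build_index, load_index, save_index

logger = logging.getLogger(__name__)

STAGES = ("ingest", "train-embeddings", "build-index", "train-classifier",
          "match", "evaluate")


class PrerequisiteError(RuntimeError):
    def __init__(self, missing: str, stage_to_run: str):
        super().__init__(
            f"missing artifact {missing!r}; run the {stage_to_run!r} stage first"
        )


@dataclass
class RunConfig:
    workdir: str = "."
    pubmed_xml: str | None = None  # glob of citation XML files
    preprints_file: str | None = None
    truth_file: str | None = None
    embedding: dict = field(default_factory=lambda: {
        "dimension": 100, "sample_fraction": 1.0, "seed": 0,
        "min_count": 2, "epochs": 5,
    })
    rules: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=lambda: {"n_pos": 100, "n_neg": 100})
    fixture: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rule_config(self) -> mt.RuleConfig:
        return mt.RuleConfig(**self.rules)

    # -- workdir paths ----------------------------------------------------
    def path(self, name: str) -> Path:
        return Path(self.workdir) / name


def _manifest_path(config: RunConfig, stage: str) -> Path:
    return config.path(f"manifest_{stage.replace('-', '_')}.json")


def _write_manifest(config: RunConfig, stage: str, counts: dict) -> dict:
    manifest = {"stage": stage, "config_hash": config.hash(), "counts": counts,
                "config": config.to_dict()}
    _manifest_path(config, stage).write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest


def _can_skip(config: RunConfig, stage: str, outputs: list[Path]) -> bool:
    mpath = _manifest_path(config, stage)
    if not mpath.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        manifest = json.loads(mpath.read_text(encoding="utf-8"))
    except json.JSONDecodeError:
        return False
    return manifest.get("config_hash") == config.hash()


def _require(config: RunConfig, name: str, stage: str) -> Path:
    p = config.path(name)
    if not p.exists():
        raise PrerequisiteError(name, stage)
    return p


# -- stage bodies ---------------------------------------------------------

def stage_fixtures(config: RunConfig) -> dict:
    cfg = fx.FixtureConfig(**config.fixture)
    preprints, papers, truth = fx.generate_corpus(cfg)
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fx.write_pubmed_xml(papers, workdir / "pubmed.xml")
    preprint_ingest.write_preprints_jsonl(preprints, workdir / "preprints.jsonl")
    fx.write_truth_jsonl(truth, workdir / "truth.jsonl")
    config.pubmed_xml = str(workdir / "pubmed.xml")
    config.preprints_file = str(workdir / "preprints.jsonl")
    config.truth_file = str(workdir / "truth.jsonl")
    return {"preprints": len(preprints), "papers": len(papers)}


def stage_ingest(config: RunConfig) -> dict:
    if config.pubmed_xml is None or config.preprints_file is None:
        raise PrerequisiteError("pubmed_xml/preprints_file config", "fixtures")
    records = []
    for path in sorted(_glob.glob(config.pubmed_xml)):
        records.extend(pubmed_ingest.parse_pubmed_xml(path))
    n_parsed = len(records)
    records = pubmed_ingest.filter_papers(records)
    pubmed_ingest.write_corpus_jsonl(records, config.path("corpus.jsonl"))
    preprints = preprint_ingest.parse_preprints(config.preprints_file)
    preprint_ingest.write_preprints_jsonl(preprints, config.path("preprints.jsonl"))
    logger.info("ingest: %d papers parsed, %d retained, %d preprints",
                n_parsed, len(records), len(preprints))
    return {"papers_parsed": n_parsed, "papers_retained": len(records),
            "preprints": len(preprints)}


def stage_train_embeddings(config: RunConfig) -> dict:
    corpus_path = _require(config, "corpus.jsonl", "ingest")
    corpus = pubmed_ingest.read_corpus_jsonl(corpus_path)
    e = config.embedding
    titles, abstracts = emb.sample_training_corpus(
        corpus, e.get("sample_fraction", 1.0), e.get("seed", 0)
    )
    kwargs = dict(
        dimension=e.get("dimension", 100), seed=e.get("seed", 0),
        min_count=e.get("min_count", 2), epochs=e.get("epochs", 5),
    )
    for kind, texts in (("title", titles), ("abstract", abstracts)):
        model = emb.train_model(texts, field_kind=kind, **kwargs)
        model.save(config.path(f"model_{kind}"))
    return {"title_texts": len(titles), "abstract_texts": len(abstracts)}


def load_models(config: RunConfig) -> dict[str, emb.EmbeddingModel]:
    models = {}
    for kind in ("title", "abstract"):
        _require(config, f"model_{kind}/model.json", "train-embeddings")
        models[kind] = emb.EmbeddingModel.load(config.path(f"model_{kind}"))
    return models


def stage_build_index(config: RunConfig) -> dict:
    corpus = pubmed_ingest.read_corpus_jsonl(_require(config, "corpus.jsonl", "ingest"))
    models = load_models(config)
    counts = {}
    for kind in ("title", "abstract"):
        texts = [
            (r.title if kind == "title" else r.abstract) or "" for r in corpus
        ]
        vectors = [emb.sentence_vector(models[kind], t) for t in texts]
        index = build_index(vectors, [r.pmid for r in corpus], field_kind=kind)
        save_index(index, config.path(f"index_{kind}"))
        counts[f"{kind}_rows"] = len(index)
    return counts


def load_indices(config: RunConfig) -> dict:
    indices = {}
    for kind in ("title", "abstract"):
        _require(config, f"index_{kind}/index.json", "build-index")
        indices[kind] = load_index(config.path(f"index_{kind}"))
    return indices


def stage_train_classifier(config: RunConfig) -> dict:
    corpus = pubmed_ingest.read_corpus_jsonl(_require(config, "corpus.jsonl", "ingest"))
    corpus_map = {r.pmid: r for r in corpus}
    preprints = preprint_ingest.parse_preprints(
        _require(config, "preprints.jsonl", "ingest")
    )
    if config.truth_file is None:
        raise PrerequisiteError("truth_file config", "fixtures")
    truth = fx.read_truth_jsonl(config.truth_file)
    models = load_models(config)
    indices = load_indices(config)
    c = config.classifier
    positives, negatives = fx.labeled_training_pairs(
        preprints, truth, models, indices, corpus_map,
        n_pos=c.get("n_pos", 100), n_neg=c.get("n_neg", 100),
        seed=c.get("seed", 0),
    )
    clf = mt.train_svm(positives, negatives, seed=c.get("seed", 0))
    payload = {"classifier": clf, "config_hash": config.hash()}
    with open(config.path("classifier.pkl"), "wb") as fh:
        pickle.dump(payload, fh)
    return {"n_pos": len(positives), "n_neg": len(negatives)}


def load_classifier(config: RunConfig) -> mt.MatchClassifier:
    path = _require(config, "classifier.pkl", "train-classifier")
    with open(path, "rb") as fh:
        return pickle.load(fh)["classifier"]


def stage_match(config: RunConfig) -> dict:
    corpus = pubmed_ingest.read_corpus_jsonl(_require(config, "corpus.jsonl", "ingest"))
    corpus_map = {r.pmid: r for r in corpus}
    preprints = preprint_ingest.parse_preprints(
        _require(config, "preprints.jsonl", "ingest")
    )
    models = load_models(config)
    indices = load_indices(config)
    classifier = load_classifier(config)
    rule_config = config.rule_config()
    n_matched = 0
    with open(config.path("matches.jsonl"), "w", encoding="utf-8") as fh:
        for preprint in preprints:
            result = mt.match(preprint, corpus_map, models, indices, classifier,
                              rule_config)
            if result.matched_pmid is not None:
                n_matched += 1
            best = next(
                (d for d in result.decision_trace if d.pmid == result.matched_pmid),
                None,
            )
            fh.write(json.dumps({
                "doi": result.preprint_doi,
                "pmid": result.matched_pmid,
                "path": best.path if best else None,
                "scores": dataclasses.asdict(best.scores) if best else None,
            }) + "\n")
    logger.info("match: %d/%d preprints matched", n_matched, len(preprints))
    return {"preprints": len(preprints), "matched": n_matched}


def read_predictions(path: str | Path) -> dict[str, str | None]:
    predictions = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                row = json.loads(line)
                predictions[row["doi"]] = row.get("pmid")
    return predictions


def truth_to_labels(truth: fx.GroundTruth) -> list[TestSetLabel]:
    return [
        TestSetLabel(doi, "true_positive" if pmid else "true_negative",
                     truth_pmid=pmid, source="curated")
        for doi, pmid in truth.items()
    ]


def stage_evaluate(config: RunConfig, compare_file: str | None = None) -> dict:
    predictions = read_predictions(_require(config, "matches.jsonl", "match"))
    if config.truth_file is None:
        raise PrerequisiteError("truth_file config", "fixtures")
    labels = truth_to_labels(fx.read_truth_jsonl(config.truth_file))
    counts = confusion_counts(predictions, labels)
    precision, recall, f1 = precision_recall_f1(counts)
    report = {
        "counts": dataclasses.asdict(counts),
        "precision": precision, "recall": recall, "f1": f1,
    }
    if compare_file:
        other = read_predictions(compare_file)
        table = discordant_table(predictions, other, labels)
        result = mcnemar_test(table)
        report["comparison"] = {
            "a": table.a, "b": table.b,
            "mcnemar_statistic": result.statistic,
            "mcnemar_exact_p": result.exact_pvalue,
        }
    config.path("report.json").write_text(
        json.dumps(report, indent=2), encoding="utf-8"
    )
    return {"evaluated": counts.total}


_STAGE_FUNCS = {
    "fixtures": stage_fixtures,
    "ingest": stage_ingest,
    "train-embeddings": stage_train_embeddings,
    "build-index": stage_build_index,
    "train-classifier": stage_train_classifier,
    "match": stage_match,
    "evaluate": stage_evaluate,
}

_STAGE_OUTPUTS = {
    "fixtures": ["pubmed.xml", "preprints.jsonl", "truth.jsonl"],
    "ingest": ["corpus.jsonl", "preprints.jsonl"],
    "train-embeddings": ["model_title/model.json", "model_abstract/model.json"],
    "build-index": ["index_title/index.json", "index_abstract/index.json"],
    "train-classifier": ["classifier.pkl"],
    "match": ["matches.jsonl"],
    "evaluate": ["report.json"],
}


def run_pipeline(
    config: RunConfig, stages: list[str], force: bool = False
) -> list[dict]:
    """Run the named stages in order, skipping completed ones."""
    manifests = []
    Path(config.workdir).mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        outputs = [config.path(n) for n in _STAGE_OUTPUTS[stage]]
        if not force and _can_skip(config, stage, outputs):
            logger.info("stage %s: up to date, skipping", stage)
            manifests.append(json.loads(
                _manifest_path(config, stage).read_text(encoding="utf-8")
            ))
            continue
        counts = _STAGE_FUNCS[stage](config)
        manifests.append(_write_manifest(config, stage, counts))
    return manifests
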