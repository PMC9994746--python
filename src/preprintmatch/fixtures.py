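"""Synthetic preprint/paper corpora with controlled revision noise.

Documents are generated from a slot grammar over topic-word pools
(subject, method, organism) plus a unique per-document marker token, so
corpora are distinguishable yet overlapping enough to create hard
negatives. Each true pair's published version applies per-token
substitution and author-list edits (add/remove/flip) at configured
rates; substitution can optionally grow with the simulated
preprint-to-paper time gap to reproduce similarity decay over time.
"""

from __future__ import annotations

import datetime as _dt
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .records import AuthorName, PaperRecord, PreprintRecord

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

# topic pools are expanded combinatorially: a large topic space keeps
# unrelated documents from crowding the top of the similarity ranking
_SUBJECT_STEMS = [
    "methyl", "autophag", "angiogen", "apopto", "chemotax",
    "glycolys", "splice", "ubiquitin", "phosphoryl", "senesc",
    "fibros", "inflamm", "neurogen", "myelin", "osmoregul",
    "photosynth", "sporul", "quiesc", "pluripot", "virul",
    "biofilm", "symbios", "thermotoler", "chemoresist", "metastas",
    "proteostas", "mitophag", "ferroptos", "exocytos", "endocytos",
    "transcript", "translat", "recombin", "segregat", "cohes",
    "condens", "acetyl", "sumoyl", "palmitoyl", "glycat",
]
SUBJECTS = [f"{stem}{suffix}" for stem in _SUBJECT_STEMS
            for suffix in ("ation", "osis", "ome", "ysis", "emia")]
_METHOD_STEMS = [
    "sequenc", "proteom", "metabolom", "microscop", "cytometr",
    "spectrometr", "crystallograph", "tomograph", "electrophysiolog",
    "optogenet", "transcriptom", "lipidom", "interferometr",
    "chromatograph", "calorimetr", "densitometr", "photometr",
    "morphometr", "stereolog", "voltammetr", "manometr", "osmometr",
    "barcod", "multiplex", "phenotyp", "genotyp", "imag",
    "model", "simulat", "screen",
]
METHODS = [f"{stem}{suffix}" for stem in _METHOD_STEMS
           for suffix in ("ing", "ics", "ery", "istry")]
_ORGANISM_STEMS = [
    "zebraf", "drosoph", "nematod", "saccharomy", "arabidops",
    "murin", "rattin", "macaqu", "xenop", "medak",
    "tardigrad", "planar", "hydr", "daphn", "parameci",
    "chlamydomon", "dictyostel", "tetrahymen", "volvoc", "euglen",
    "salmonell", "lister", "vibrion", "bacill", "streptomyc",
]
ORGANISMS = [f"{stem}{suffix}" for stem in _ORGANISM_STEMS
             for suffix in ("ids", "ians", "ella", "ates")]
FILLERS = [
    "analysis", "reveals", "dynamics", "pathway", "network", "response",
    "regulation", "control", "signal", "factor", "complex", "domain",
    "profile", "pattern", "variation", "structure", "function", "activity",
    "expression", "levels", "samples", "cells", "tissue", "stress",
    "growth", "development", "adaptation", "interaction", "mechanism",
    "model", "approach", "framework", "evidence", "results", "data",
    "robust", "novel", "distinct", "conserved", "specific", "global",
    "during", "under", "across", "within", "between", "through",
]
# name pools are built combinatorially so that accidental author overlap
# between unrelated records is as rare as in a real corpus
_FORE_STEMS = [
    "Ada", "Boris", "Chen", "Dara", "Emil", "Farah", "Goran", "Hana",
    "Igor", "Jana", "Kenji", "Lena", "Marco", "Nadia", "Omar", "Priya",
    "Quinn", "Rosa", "Sven", "Tara", "Ulf", "Vera", "Wei", "Xenia",
    "Yuki", "Zola", "Anders", "Bela", "Carmen", "Dmitri", "Elena", "Felix",
]
_LAST_PREFIXES = [
    "Alm", "Berg", "Cast", "Dub", "Erik", "Font", "Grim", "Hoff", "Ivan",
    "Jans", "Kowal", "Lind", "Mor", "Nov", "Oka", "Petr", "Quint", "Ross",
    "Schn", "Taka", "Ued", "Vasq", "Web", "Xia", "Yama", "Zhan", "Ander",
    "Bian", "Cost", "Dvor", "Ekl", "Ferr", "Gall", "Hadd", "Ibra", "Johan",
    "Kim", "Lars", "Meht", "Nguy",
]
_LAST_SUFFIXES = [
    "eida", "strom", "illo", "ois", "sen", "aine", "aldi", "mann", "ova",
    "son", "ski", "qvist", "etti", "ak", "for", "ov", "ana", "si", "eider",
    "hashi", "eda", "uez", "er", "u", "moto", "g", "sen", "chi", "a",
    "ak", "und", "eira", "o", "ad", "him", "sson", "ura", "on", "a", "en",
]
FORE_NAMES = [f"{stem}{suffix}" for stem in _FORE_STEMS
              for suffix in ("", "r", "n", "l", "s", "t", "m", "d", "k", "v")]
LAST_NAMES = sorted({f"{p}{s}" for p in _LAST_PREFIXES for s in _LAST_SUFFIXES})


def default_vocab() -> dict[str, list[str]]:
    return {
        "subjects": list(SUBJECTS),
        "methods": list(METHODS),
        "organisms": list(ORGANISMS),
        "fillers": list(FILLERS),
    }


@dataclass
class FixtureConfig:
    n_pairs: int = 50
    n_decoys: int = 50
    n_unpublished: int = 20
    vocab: dict[str, list[str]] | None = None
    text_sub_rate: float = 0.0
    author_add_rate: float = 0.0
    author_remove_rate: float = 0.0
    author_flip_rate: float = 0.0
    gap_days: tuple[int, int] = (7, 400)
    #: extra substitution probability per day of gap (Fig-3-style decay)
    gap_sub_slope: float = 0.0
    announce_rate: float = 0.5
    large_authorset_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.vocab = self.vocab or default_vocab()
        if any(not pool for pool in self.vocab.values()):
            raise ValueError("vocab pools must be non-empty")
        for name in ("text_sub_rate", "author_add_rate", "author_remove_rate",
                     "author_flip_rate", "announce_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.author_remove_rate >= 1.0 and self.n_pairs > 0:
            raise ValueError("author_remove_rate of 1 would empty author lists")
        if min(self.n_pairs, self.n_decoys, self.n_unpublished) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class GroundTruth:
    """preprint doi → pmid of the published version, or None."""

    mapping: dict[str, str | None] = dc_field(default_factory=dict)

    def __getitem__(self, doi: str) -> str | None:
        return self.mapping[doi]

    def __len__(self) -> int:
        return len(self.mapping)

    def items(self):
        return self.mapping.items()


def _make_authors(rng: np.random.Generator, large: bool) -> list[AuthorName]:
    n = int(rng.integers(11, 16)) if large else int(rng.integers(2, 7))
    idx_f = rng.choice(len(FORE_NAMES), size=n, replace=True)
    idx_l = rng.choice(len(LAST_NAMES), size=n, replace=False)
    return [
        AuthorName(fore_name=FORE_NAMES[i], last_name=LAST_NAMES[j])
        for i, j in zip(idx_f, idx_l)
    ]


def _edit_authors(
    authors: list[AuthorName], cfg: FixtureConfig, rng: np.random.Generator
) -> list[AuthorName]:
    edited: list[AuthorName] = []
    for a in authors:
        if cfg.author_remove_rate > 0 and rng.random() < cfg.author_remove_rate:
            continue
        if cfg.author_flip_rate > 0 and a.fore_name and rng.random() < cfg.author_flip_rate:
            edited.append(AuthorName(fore_name=a.last_name, last_name=a.fore_name))
        else:
            edited.append(a)
    if not edited:
        edited = [authors[int(rng.integers(len(authors)))]]
    if cfg.author_add_rate > 0 and rng.random() < cfg.author_add_rate:
        edited.append(
            AuthorName(
                fore_name=FORE_NAMES[int(rng.integers(len(FORE_NAMES)))],
                last_name=LAST_NAMES[int(rng.integers(len(LAST_NAMES)))],
            )
        )
    return edited


def _make_texts(
    rng: np.random.Generator, vocab: dict[str, list[str]], uid: int
) -> tuple[str, str]:
    subjects = vocab["subjects"]
    s1, s2 = (subjects[int(i)] for i in rng.choice(len(subjects), 2, replace=False))
    method = vocab["methods"][int(rng.integers(len(vocab["methods"])))]
    organism = vocab["organisms"][int(rng.integers(len(vocab["organisms"])))]
    marker = f"assay{uid}"

    if rng.random() < 0.3:
        title = f"tool{uid}: {method} analysis of {s1} in {organism}"
    else:
        title = f"{method} analysis of {s1} and {s2} in {organism}"

    fillers = vocab["fillers"]
    # stable opening sentence (exercises the 7-word prefix rule), then a
    # topic-dominated body so documents are distinguishable
    opening = f"Using {marker} we study {s1} and {s2} in {organism}."
    body = (
        [s1] * 5 + [s2] * 4 + [method] * 4 + [organism] * 4 + [marker] * 2
        + [fillers[int(i)] for i in rng.choice(len(fillers), 14)]
    )
    body = [body[int(i)] for i in rng.permutation(len(body))]
    return title, opening + " " + " ".join(body) + "."


def _substitute_tokens(
    text: str, rate: float, pool: list[str], rng: np.random.Generator
) -> str:
    if rate <= 0:
        return text
    tokens = text.split()
    out = []
    for tok in tokens:
        if rng.random() < rate:
            out.append(pool[int(rng.integers(len(pool)))])
        else:
            out.append(tok)
    return " ".join(out)


def generate_corpus(
    config: FixtureConfig,
) -> tuple[list[PreprintRecord], list[PaperRecord], GroundTruth]:
    """Generate preprints, papers and the linkage ground truth.

    ``|preprints| = n_pairs + n_unpublished``; ``|papers| = n_pairs +
    n_decoys``. Fully reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    vocab = config.vocab
    all_pool = sum(vocab.values(), [])

    preprints: list[PreprintRecord] = []
    papers: list[PaperRecord] = []
    truth = GroundTruth()
    base_date = _dt.date(2019, 1, 6)
    uid = 0

    for i in range(config.n_pairs):
        uid += 1
        title, abstract = _make_texts(rng, vocab, uid)
        large = rng.random() < config.large_authorset_fraction
        authors = _make_authors(rng, large)
        posted = base_date + _dt.timedelta(days=int(rng.integers(0, 700)))
        gap = int(rng.integers(config.gap_days[0], config.gap_days[1] + 1))
        doi = f"10.1101/2020.{uid:06d}"
        pmid = f"{1000000 + uid}"

        eff_rate = min(1.0, config.text_sub_rate + config.gap_sub_slope * gap)
        paper_title = _substitute_tokens(title, eff_rate, all_pool, rng)
        paper_abstract = _substitute_tokens(abstract, eff_rate, all_pool, rng)
        paper_authors = _edit_authors(authors, config, rng)
        announced = rng.random() < config.announce_rate

        preprints.append(
            PreprintRecord(
                doi=doi, title=title, abstract=abstract, posted_date=posted,
                authors=authors, announced_pub_id=pmid if announced else None,
            )
        )
        papers.append(
            PaperRecord(
                pmid=pmid, doi=f"10.1000/j.{uid:06d}", title=paper_title,
                abstract=paper_abstract, pub_date=posted + _dt.timedelta(days=gap),
                authors=paper_authors, language_codes={"eng"},
                publication_types={"Journal Article"},
            )
        )
        truth.mapping[doi] = pmid

    for _ in range(config.n_decoys):
        uid += 1
        title, abstract = _make_texts(rng, vocab, uid)
        papers.append(
            PaperRecord(
                pmid=f"{1000000 + uid}", doi=f"10.1000/j.{uid:06d}", title=title,
                abstract=abstract,
                pub_date=base_date + _dt.timedelta(days=int(rng.integers(0, 1000))),
                authors=_make_authors(rng, rng.random() < config.large_authorset_fraction),
                language_codes={"eng"}, publication_types={"Journal Article"},
            )
        )

    for _ in range(config.n_unpublished):
        uid += 1
        title, abstract = _make_texts(rng, vocab, uid)
        doi = f"10.1101/2020.{uid:06d}"
        preprints.append(
            PreprintRecord(
                doi=doi, title=title, abstract=abstract,
                posted_date=base_date + _dt.timedelta(days=int(rng.integers(0, 700))),
                authors=_make_authors(rng, False),
            )
        )
        truth.mapping[doi] = None

    order = rng.permutation(len(papers))
    papers = [papers[int(i)] for i in order]
    return preprints, papers, truth


def write_pubmed_xml(papers: list[PaperRecord], path: str | Path) -> None:
    """Emit citation-dialect XML that ``parse_pubmed_xml`` round-trips."""
    root = ET.Element("PubmedArticleSet")
    for paper in papers:
        art_el = ET.SubElement(root, "PubmedArticle")
        citation = ET.SubElement(art_el, "MedlineCitation")
        ET.SubElement(citation, "PMID").text = paper.pmid
        article = ET.SubElement(citation, "Article")
        journal = ET.SubElement(article, "Journal")
        issue = ET.SubElement(journal, "JournalIssue")
        pubdate = ET.SubElement(issue, "PubDate")
        ET.SubElement(pubdate, "Year").text = str(paper.pub_date.year)
        ET.SubElement(pubdate, "Month").text = _MONTH_ABBR[paper.pub_date.month - 1]
        ET.SubElement(pubdate, "Day").text = str(paper.pub_date.day)
        if paper.title is not None:
            ET.SubElement(article, "ArticleTitle").text = paper.title
        if paper.abstract is not None:
            abstract = ET.SubElement(article, "Abstract")
            ET.SubElement(abstract, "AbstractText").text = paper.abstract
        if paper.authors:
            author_list = ET.SubElement(article, "AuthorList")
            for a in paper.authors:
                author = ET.SubElement(author_list, "Author")
                ET.SubElement(author, "LastName").text = a.last_name
                if a.fore_name:
                    ET.SubElement(author, "ForeName").text = a.fore_name
        for lang in sorted(paper.language_codes):
            ET.SubElement(article, "Language").text = lang
        ptl = ET.SubElement(article, "PublicationTypeList")
        for pt in sorted(paper.publication_types):
            ET.SubElement(ptl, "PublicationType").text = pt
        if paper.doi is not None:
            pubmed_data = ET.SubElement(art_el, "PubmedData")
            id_list = ET.SubElement(pubmed_data, "ArticleIdList")
            aid = ET.SubElement(id_list, "ArticleId")
            aid.set("IdType", "doi")
            aid.text = paper.doi
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def write_truth_jsonl(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doi, pmid in truth.items():
            fh.write(json.dumps({"doi": doi, "pmid": pmid}) + "\n")


def read_truth_jsonl(path: str | Path) -> GroundTruth:
    truth = GroundTruth()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                row = json.loads(line)
                truth.mapping[row["doi"]] = row["pmid"]
    return truth


def labeled_training_pairs(
    preprints: list[PreprintRecord],
    truth: GroundTruth,
    models: dict,
    indices: dict,
    corpus: dict[str, PaperRecord],
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> tuple[list, list]:
    """Feature-labeled training pairs; fixture truth stands in for curation.

    Positives come from true pairs; negatives from hard-negative mining
    with any truth-matching pair removed automatically. Raises on
    shortfall.
    """
    from .author_match import author_score
    from .embeddings import sentence_vector
    from .matcher import CandidateScore, mine_hard_negatives

    rng = np.random.default_rng(seed)
    true_pairs = [(p, truth[p.doi]) for p in preprints if truth[p.doi] is not None]
    if len(true_pairs) < n_pos:
        raise ValueError(
            f"need {n_pos} positive pairs, corpus has {len(true_pairs)}"
        )
    pick = rng.choice(len(true_pairs), size=n_pos, replace=False)
    positives = []
    for i in pick:
        preprint, pmid = true_pairs[int(i)]
        paper = corpus[pmid]
        t = float(np.dot(
            sentence_vector(models["title"], preprint.title).values,
            sentence_vector(models["title"], paper.title or "").values,
        ))
        a = float(np.dot(
            sentence_vector(models["abstract"], preprint.abstract).values,
            sentence_vector(models["abstract"], paper.abstract or "").values,
        ))
        positives.append(
            CandidateScore(
                pmid=pmid, title_sim=t, abstract_sim=a,
                author_sim=author_score(preprint.authors, paper.authors).score,
            )
        )

    unpublished = [p for p in preprints if truth[p.doi] is None]
    mined = mine_hard_negatives(unpublished, models, indices, corpus)
    negatives = [
        score for doi, score in mined if truth[doi] != score.pmid
    ][:n_neg]
    if len(negatives) < n_neg:
        raise ValueError(
            f"need {n_neg} negative pairs, mining produced {len(negatives)}"
        )
    return positives, negatives
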