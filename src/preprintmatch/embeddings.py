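"""Subword-aware word embeddings and sentence vectors.

Separate models are trained for titles and abstracts on a random sample
of the corpus. Training is skip-gram with negative sampling; every word
is represented as the mean of its own vector and its character n-gram
(3-6) vectors, so out-of-vocabulary tokens can still be embedded by
composing the n-grams they share with training words.

A text maps to a sentence vector by averaging its token vectors and
scaling to unit norm; texts with no embeddable token map to the zero
vector, flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .records import PaperRecord

logger = logging.getLogger(__name__)

_PUNCT_TABLE = str.maketrans(
    {c: " " for c in "!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~“”‘’—–"}
)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation to spaces, split on whitespace."""
    return text.lower().translate(_PUNCT_TABLE).split()


def char_ngrams(word: str, minn: int = 3, maxn: int = 6) -> list[str]:
    """Character n-grams of ``<word>`` including boundary markers."""
    wrapped = f"<{word}>"
    grams = []
    for n in range(minn, maxn + 1):
        if n > len(wrapped):
            break
        for i in range(len(wrapped) - n + 1):
            grams.append(wrapped[i : i + n])
    return grams


@dataclass
class SentenceVector:
    values: np.ndarray
    is_zero: bool

    @property
    def norm_flag(self) -> bool:
        """True when the vector is unit-normalized (i.e. not the zero fallback)."""
        return not self.is_zero


@njit(cache=True)
def _sgns_train(tokens, offsets, sub_idx, sub_ptr, in_mat, out_mat,
                neg_table, keep_prob, window, negatives, epochs, lr0, seed):
    np.random.seed(seed)
    dim = in_mat.shape[1]
    n_sent = offsets.shape[0] - 1
    n_tokens = tokens.shape[0]
    total = max(1, epochs * n_tokens)
    processed = 0
    hidden = np.empty(dim, dtype=np.float32)
    gradh = np.empty(dim, dtype=np.float32)
    sent_buf = np.empty(n_tokens, dtype=np.int64)
    for _ep in range(epochs):
        for s in range(n_sent):
            # frequent-word subsampling, resampled each epoch
            end = 0
            for i in range(offsets[s], offsets[s + 1]):
                tok = tokens[i]
                if keep_prob[tok] >= 1.0 or np.random.random() < keep_prob[tok]:
                    sent_buf[end] = tok
                    end += 1
            start = 0
            for i in range(start, end):
                center = sent_buf[i]
                lr = lr0 * (1.0 - processed / total)
                if lr < lr0 * 1e-4:
                    lr = lr0 * 1e-4
                processed += 1
                b = 1 + np.random.randint(window)
                lo = i - b
                if lo < start:
                    lo = start
                hi = i + b + 1
                if hi > end:
                    hi = end
                p0 = sub_ptr[center]
                p1 = sub_ptr[center + 1]
                nsub = p1 - p0
                if nsub == 0:
                    continue
                for j in range(lo, hi):
                    if j == i:
                        continue
                    target = sent_buf[j]
                    for d in range(dim):
                        hidden[d] = 0.0
                        gradh[d] = 0.0
                    for k in range(p0, p1):
                        row = sub_idx[k]
                        for d in range(dim):
                            hidden[d] += in_mat[row, d]
                    for d in range(dim):
                        hidden[d] /= nsub
                    for n in range(negatives + 1):
                        if n == 0:
                            t = target
                            label = 1.0
                        else:
                            t = neg_table[np.random.randint(neg_table.shape[0])]
                            if t == target:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += hidden[d] * out_mat[t, d]
                        if dot > 8.0:
                            f = 1.0
                        elif dot < -8.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - f) * lr
                        for d in range(dim):
                            gradh[d] += g * out_mat[t, d]
                            out_mat[t, d] += g * hidden[d]
                    for d in range(dim):
                        gradh[d] /= nsub
                    for k in range(p0, p1):
                        row = sub_idx[k]
                        for d in range(dim):
                            in_mat[row, d] += gradh[d]


@dataclass
class EmbeddingModel:
    """A trained subword embedding model for one text field."""

    field_kind: str
    dimension: int
    words: list[str]
    ngrams: list[str]
    in_mat: np.ndarray  # (n_words + n_ngrams, dim); word rows first
    train_seed: int = 0
    train_sample_size: int = 0
    hyperparams: dict = field(default_factory=dict)
    _word_index: dict = field(default_factory=dict, repr=False)
    _ngram_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._word_index:
            self._word_index = {w: i for i, w in enumerate(self.words)}
        if not self._ngram_index:
            offset = len(self.words)
            self._ngram_index = {g: offset + i for i, g in enumerate(self.ngrams)}

    @property
    def minn(self) -> int:
        return self.hyperparams.get("minn", 3)

    @property
    def maxn(self) -> int:
        return self.hyperparams.get("maxn", 6)

    def token_vector(self, token: str) -> np.ndarray | None:
        """Compose a token's vector; None when nothing is embeddable."""
        rows = []
        idx = self._word_index.get(token)
        if idx is not None:
            rows.append(idx)
        for gram in char_ngrams(token, self.minn, self.maxn):
            gidx = self._ngram_index.get(gram)
            if gidx is not None:
                rows.append(gidx)
        if not rows:
            return None
        return self.in_mat[rows].mean(axis=0)

    def sentence_vector(self, text: str) -> SentenceVector:
        return sentence_vector(self, text)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.in_mat.astype("<f4").tofile(directory / "vectors.f32")
        meta = {
            "field_kind": self.field_kind,
            "dimension": self.dimension,
            "words": self.words,
            "ngrams": self.ngrams,
            "train_seed": self.train_seed,
            "train_sample_size": self.train_sample_size,
            "hyperparams": self.hyperparams,
        }
        (directory / "model.json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
        n_rows = len(meta["words"]) + len(meta["ngrams"])
        mat = np.fromfile(directory / "vectors.f32", dtype="<f4").reshape(
            n_rows, meta["dimension"]
        )
        return cls(
            field_kind=meta["field_kind"],
            dimension=meta["dimension"],
            words=meta["words"],
            ngrams=meta["ngrams"],
            in_mat=mat,
            train_seed=meta["train_seed"],
            train_sample_size=meta["train_sample_size"],
            hyperparams=meta["hyperparams"],
        )


def sample_texts(texts: list[str], fraction: float, seed: int) -> list[str]:
    """Simple random sample without replacement of ``floor(n*fraction)`` texts."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not texts:
        raise ValueError("cannot sample from an empty corpus")
    rng = np.random.default_rng(seed)
    n = int(len(texts) * fraction)
    if fraction == 1.0:
        n = len(texts)
    idx = rng.choice(len(texts), size=n, replace=False)
    return [texts[i] for i in idx]


def sample_training_corpus(
    corpus: list[PaperRecord], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Sample title and abstract training pools independently."""
    titles = [r.title for r in corpus if r.title]
    abstracts = [r.abstract for r in corpus if r.abstract]
    if not titles and not abstracts:
        raise ValueError("corpus has no embeddable text")
    title_pool = sample_texts(titles, fraction, seed) if titles else []
    # distinct stream per field so the two samples are independent
    abstract_pool = (
        sample_texts(abstracts, fraction, seed + 1) if abstracts else []
    )
    return title_pool, abstract_pool


def train_model(
    texts: list[str],
    field_kind: str,
    dimension: int = 300,
    seed: int = 0,
    min_count: int = 5,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.05,
    minn: int = 3,
    maxn: int = 6,
    subsample: float = 1e-3,
    remove_components: int = 1,
) -> EmbeddingModel:
    """Train a subword skip-gram model; deterministic for a fixed seed.

    Training is single-threaded by construction, so two runs with the
    same texts and seed produce identical vectors.

    After training, the mean and the top ``remove_components`` principal
    directions of the composed vocabulary vectors are removed from every
    stored row (all-but-the-top post-processing). Small templated
    corpora otherwise collapse onto a single shared direction — common
    character n-grams act as hubs — which saturates every cosine near 1
    and destroys ranking. The transform is affine over rows, so
    out-of-vocabulary composition stays consistent.
    """
    tokenized = [tokenize(t) for t in texts if t]
    tokenized = [toks for toks in tokenized if toks]
    if not tokenized:
        raise ValueError("no non-empty training texts")

    counts: dict[str, int] = {}
    for toks in tokenized:
        for tok in toks:
            counts[tok] = counts.get(tok, 0) + 1
    words = sorted(w for w, c in counts.items() if c >= min_count)
    if not words:
        raise ValueError(
            f"min_count={min_count} removed every token; lower it for small corpora"
        )
    word_index = {w: i for i, w in enumerate(words)}

    ngram_set: set[str] = set()
    for w in words:
        ngram_set.update(char_ngrams(w, minn, maxn))
    ngrams = sorted(ngram_set)
    ngram_index = {g: len(words) + i for i, g in enumerate(ngrams)}

    # flattened subword lists: word row itself + its n-gram rows
    sub_idx_list: list[int] = []
    sub_ptr = np.zeros(len(words) + 1, dtype=np.int64)
    for i, w in enumerate(words):
        rows = [i] + [ngram_index[g] for g in char_ngrams(w, minn, maxn)]
        sub_idx_list.extend(rows)
        sub_ptr[i + 1] = len(sub_idx_list)
    sub_idx = np.asarray(sub_idx_list, dtype=np.int64)

    token_arrays = []
    offsets = [0]
    for toks in tokenized:
        ids = [word_index[t] for t in toks if t in word_index]
        token_arrays.extend(ids)
        offsets.append(len(token_arrays))
    tokens = np.asarray(token_arrays, dtype=np.int64)
    offsets_arr = np.asarray(offsets, dtype=np.int64)
    if tokens.size == 0:
        raise ValueError("no in-vocabulary tokens to train on")

    # unigram^0.75 negative-sampling table
    freq = np.array([counts[w] for w in words], dtype=np.float64) ** 0.75
    probs = freq / freq.sum()
    table_size = max(1000, 10 * len(words))
    neg_table = np.repeat(
        np.arange(len(words), dtype=np.int64),
        np.maximum(1, np.round(probs * table_size).astype(np.int64)),
    )

    # frequent-word subsampling keep probabilities (word2vec formula)
    if subsample > 0:
        f = np.array([counts[w] for w in words], dtype=np.float64) / tokens.size
        keep_prob = np.minimum(1.0, np.sqrt(subsample / f) + subsample / f)
    else:
        keep_prob = np.ones(len(words), dtype=np.float64)

    rng = np.random.default_rng(seed)
    n_rows = len(words) + len(ngrams)
    in_mat = (
        (rng.random((n_rows, dimension), dtype=np.float32) - 0.5) / dimension
    ).astype(np.float32)
    out_mat = np.zeros((len(words), dimension), dtype=np.float32)

    _sgns_train(
        tokens, offsets_arr, sub_idx, sub_ptr, in_mat, out_mat, neg_table,
        keep_prob, window, negatives, epochs, learning_rate, seed,
    )

    if remove_components > 0:
        # compose vocab vectors with the same rule token_vector uses
        composed = np.empty((len(words), dimension), dtype=np.float64)
        for i in range(len(words)):
            rows = sub_idx[sub_ptr[i]:sub_ptr[i + 1]]
            composed[i] = in_mat[rows].mean(axis=0)
        mu = composed.mean(axis=0)
        in_mat = in_mat - mu.astype(np.float32)
        centered = composed - mu
        if len(words) > 1:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            top = vt[: min(remove_components, vt.shape[0])].astype(np.float32)
            in_mat = in_mat - (in_mat @ top.T) @ top

    return EmbeddingModel(
        field_kind=field_kind,
        dimension=dimension,
        words=words,
        ngrams=ngrams,
        in_mat=in_mat,
        train_seed=seed,
        train_sample_size=len(tokenized),
        hyperparams={
            "min_count": min_count,
            "window": window,
            "negatives": negatives,
            "epochs": epochs,
            "learning_rate": learning_rate,
            "minn": minn,
            "maxn": maxn,
            "subsample": subsample,
            "remove_components": remove_components,
        },
    )


def sentence_vector(model: EmbeddingModel, text: str) -> SentenceVector:
    """Normalized average of the text's token vectors; zero if none embed.

    Each token vector is scaled to unit norm before averaging (so no
    single token dominates the mean), and the average is scaled to unit
    norm afterwards.
    """
    vecs = []
    for tok in tokenize(text or ""):
        v = model.token_vector(tok)
        if v is not None:
            n = float(np.linalg.norm(v))
            if n > 0:
                vecs.append(v / n)
    if not vecs:
        return SentenceVector(
            values=np.zeros(model.dimension, dtype=np.float32), is_zero=True
        )
    mean = np.mean(vecs, axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        return SentenceVector(
            values=np.zeros(model.dimension, dtype=np.float32), is_zero=True
        )
    return SentenceVector(values=(mean / norm).astype(np.float32), is_zero=False)
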