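"""Out-of-core vector index with exhaustive top-k cosine retrieval.

The index is a raw little-endian float32 matrix file (one unit- or
zero-norm row per paper) plus a JSON sidecar holding the aligned PMID
list, dimension and field kind. Rows are accessed through ``np.memmap``
so retrieval never requires the whole matrix in working memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embeddings import SentenceVector

MATRIX_FILE = "matrix.f32"
SIDECAR_FILE = "index.json"


@dataclass
class VectorIndex:
    field_kind: str
    matrix: np.ndarray  # (n, dim) memmap or ndarray; rows unit or zero norm
    row_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.row_ids):
            raise ValueError("row count must equal id count")

    @property
    def dimension(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.row_ids)

    def row_of(self, pmid: str) -> np.ndarray:
        """The stored (unit or zero) vector for one paper."""
        if not hasattr(self, "_positions"):
            self._positions = {p: i for i, p in enumerate(self.row_ids)}
        return np.asarray(self.matrix[self._positions[pmid]])


@dataclass
class CandidateSet:
    """Union of title and abstract top-k lists with provenance flags."""

    pmids: set[str]
    provenance: dict[str, set[str]]  # pmid -> subset of {from_title_topk, from_abstract_topk}


def build_index(
    vectors: list[SentenceVector] | np.ndarray,
    ids: list[str],
    directory: str | Path | None = None,
    field_kind: str = "title",
) -> VectorIndex:
    """Assemble (and optionally persist) an index from sentence vectors."""
    if isinstance(vectors, np.ndarray):
        matrix = np.ascontiguousarray(vectors, dtype=np.float32)
    else:
        if len(vectors) == 0:
            raise ValueError("cannot build an index from no vectors")
        dims = {v.values.shape[0] for v in vectors}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        matrix = np.stack([v.values for v in vectors]).astype(np.float32)
    if matrix.size == 0:
        raise ValueError("cannot build an index from no vectors")
    if matrix.shape[0] != len(ids):
        raise ValueError("vectors and ids must have equal length")
    index = VectorIndex(field_kind=field_kind, matrix=matrix, row_ids=list(ids))
    if directory is not None:
        save_index(index, directory)
    return index


def save_index(index: VectorIndex, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(index.matrix, dtype="<f4").tofile(directory / MATRIX_FILE)
    sidecar = {
        "field_kind": index.field_kind,
        "dimension": index.dimension,
        "row_ids": index.row_ids,
    }
    (directory / SIDECAR_FILE).write_text(json.dumps(sidecar), encoding="utf-8")


def load_index(directory: str | Path) -> VectorIndex:
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_FILE).read_text(encoding="utf-8"))
    n = len(sidecar["row_ids"])
    matrix = np.memmap(
        directory / MATRIX_FILE,
        dtype="<f4",
        mode="r",
        shape=(n, sidecar["dimension"]),
    )
    return VectorIndex(
        field_kind=sidecar["field_kind"],
        matrix=matrix,
        row_ids=sidecar["row_ids"],
    )


def cosine_scores(index: VectorIndex, query: SentenceVector | np.ndarray) -> np.ndarray:
    """Cosine of the query against every row (rows and query unit-norm)."""
    q = query.values if isinstance(query, SentenceVector) else np.asarray(query)
    if q.shape[0] != index.dimension:
        raise ValueError(
            f"query dimension {q.shape[0]} != index dimension {index.dimension}"
        )
    return np.asarray(index.matrix) @ q.astype(np.float32)


def top_k_cosine(
    index: VectorIndex, query: SentenceVector | np.ndarray, k: int = 100
) -> list[tuple[str, float]]:
    """The k most cosine-similar rows, nonincreasing; ties by ascending pmid."""
    if k <= 0:
        raise ValueError("k must be positive")
    sims = cosine_scores(index, query)
    k = min(k, len(index))
    ids = np.asarray(index.row_ids)
    order = np.lexsort((ids, -sims))
    top = order[:k]
    return [(str(ids[i]), float(sims[i])) for i in top]


def candidate_union(
    title_topk: list[tuple[str, float]],
    abstract_topk: list[tuple[str, float]],
) -> CandidateSet:
    """Union of the two top-k lists, keeping which list each pmid came from."""
    provenance: dict[str, set[str]] = {}
    for pmid, _ in title_topk:
        provenance.setdefault(pmid, set()).add("from_title_topk")
    for pmid, _ in abstract_topk:
        provenance.setdefault(pmid, set()).add("from_abstract_topk")
    return CandidateSet(pmids=set(provenance), provenance=provenance)
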