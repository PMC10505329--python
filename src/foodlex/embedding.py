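"""Word-embedding spaces in word2vec format, with cosine-similarity search.

The on-disk formats are the classic word2vec conventions: a header line
``"<vocab_size> <dim>"`` followed either by text rows (``word v1 ... vd``) or,
in binary mode, by ``word`` + space + ``dim`` little-endian float32 values per
entry. Raw vectors are kept as loaded (they feed the mixture model and the
classifiers); a unit-normalized copy is built lazily for cosine search, which
is scale-free anyway.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmbeddingSpace",
    "EmbeddingFormatError",
    "load_embeddings",
    "save_embeddings",
    "cosine_similarity",
    "neighbors_within",
]

logger = logging.getLogger(__name__)


class EmbeddingFormatError(ValueError):
    """Malformed word2vec file (bad header, count mismatch, duplicate word)."""


class EmbeddingSpace:
    """An ordered vocabulary with one fixed-dimension vector per word."""

    def __init__(self, words: Sequence[str], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or len(words) != vectors.shape[0]:
            raise ValueError("words and vectors must align: one row per word")
        if len(words) == 0:
            raise ValueError("empty vocabulary")
        self.words: list[str] = list(words)
        self.vectors = vectors
        self.index: dict[str, int] = {}
        for i, w in enumerate(self.words):
            if w in self.index:
                raise EmbeddingFormatError(f"duplicate word {w!r}")
            self.index[w] = i
        self._unit: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index[word]]

    @property
    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the matrix (built once, cached)."""
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            if np.any(norms == 0):
                zero = self.words[int(np.argmin(norms))]
                raise ValueError(f"zero vector for word {zero!r}")
            self._unit = self.vectors / norms
        return self._unit

    def subset(self, words: Iterable[str]) -> tuple[list[str], np.ndarray]:
        """In-vocabulary words (original order kept) and their vector rows."""
        kept = [w for w in words if w in self.index]
        rows = np.array([self.index[w] for w in kept], dtype=int)
        return kept, self.vectors[rows] if len(rows) else np.empty((0, self.d))


def load_embeddings(path: str | Path, format: str = "word2vec_text") -> EmbeddingSpace:
    """Read a word2vec text or binary file into an :class:`EmbeddingSpace`.

    The header's declared vocabulary size and dimension are enforced; lookup
    is case-sensitive, matching how pretrained news-corpus models distinguish
    e.g. proper-noun phrases from plain words.
    """
    path = Path(path)
    if format == "word2vec_text":
        return _load_text(path)
    if format == "word2vec_binary":
        return _load_binary(path)
    raise ValueError(f"unknown format {format!r}")


def _parse_header(line: bytes | str) -> tuple[int, int]:
    parts = (line.decode() if isinstance(line, bytes) else line).split()
    if len(parts) != 2:
        raise EmbeddingFormatError(f"bad header {line!r}")
    n, d = int(parts[0]), int(parts[1])
    if n < 1 or d < 1:
        raise EmbeddingFormatError(f"bad header counts {n} {d}")
    return n, d


def _load_text(path: Path) -> EmbeddingSpace:
    with open(path, "r", encoding="utf-8") as fh:
        n, d = _parse_header(fh.readline())
        words: list[str] = []
        vecs = np.empty((n, d))
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            if i >= n:
                raise EmbeddingFormatError(f"more than the declared {n} rows")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise EmbeddingFormatError(
                    f"row {i}: expected {d} values, got {len(parts) - 1}"
                )
            words.append(parts[0])
            vecs[i] = [float(x) for x in parts[1:]]
    if len(words) != n:
        raise EmbeddingFormatError(f"header declares {n} words, file has {len(words)}")
    return EmbeddingSpace(words, vecs)


def _load_binary(path: Path) -> EmbeddingSpace:
    with open(path, "rb") as fh:
        n, d = _parse_header(fh.readline())
        words: list[str] = []
        vecs = np.empty((n, d), dtype=np.float32)
        for i in range(n):
            chars = bytearray()
            while True:
                c = fh.read(1)
                if not c:
                    raise EmbeddingFormatError(
                        f"header declares {n} words, file has {i}"
                    )
                if c == b" ":
                    break
                if c != b"\n":  # tolerate newline between entries
                    chars.extend(c)
            row = np.frombuffer(fh.read(4 * d), dtype="<f4")
            if row.size != d:
                raise EmbeddingFormatError(f"truncated vector for row {i}")
            words.append(chars.decode("utf-8"))
            vecs[i] = row
    return EmbeddingSpace(words, vecs)


def save_embeddings(
    space: EmbeddingSpace, path: str | Path, format: str = "word2vec_text"
) -> None:
    """Write the space back out in word2vec text or binary format."""
    path = Path(path)
    if format == "word2vec_text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(space)} {space.d}\n")
            for w, v in zip(space.words, space.vectors):
                fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")
    elif format == "word2vec_binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(space)} {space.d}\n".encode())
            for w, v in zip(space.words, space.vectors):
                fh.write(w.encode("utf-8") + b" ")
                fh.write(np.asarray(v, dtype="<f4").tobytes())
    else:
        raise ValueError(f"unknown format {format!r}")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def neighbors_within(
    space: EmbeddingSpace, query: np.ndarray, s: float
) -> list[tuple[str, float]]:
    """All vocabulary words with cosine similarity >= ``s`` to ``query``.

    A full scan against the precomputed normalized matrix — exact by
    construction, no approximate index. Sorted by similarity descending,
    ties broken lexicographically.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"similarity level must be in [0, 1], got {s}")
    query = np.asarray(query, dtype=float)
    nq = np.linalg.norm(query)
    if nq == 0:
        raise ValueError("cosine similarity undefined for a zero query")
    sims = space.unit_vectors @ (query / nq)
    hits = np.flatnonzero(sims >= s)
    out = [(space.words[i], float(sims[i])) for i in hits]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
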