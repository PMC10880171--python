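"""Dense semantic similarity: embedder contract, toy backend, vector files.

Semantic similarity between a query and a candidate concept is the cosine
of their dense vectors.  In production those vectors come from a
biomedical language model (SapBERT-class) using the sequence-start special
token of the final layer as the whole-sequence embedding; here the model
is behind a minimal contract — ``name``, ``dim``, ``embed(texts) ->
(len(texts), dim) array`` — with two shipped backends:

* :class:`PrecomputedEmbedder` loads a term -> vector table produced
  offline (the supported route for real language-model vectors);
* :func:`hashed_ngram_embedder` is a deterministic toy backend that embeds
  a text as the l2-normalized sum of seeded pseudo-random unit vectors
  hashed from its character 3-grams, so texts sharing many 3-grams get a
  high cosine.  It exists so every downstream stage is testable with no
  model download.

Embedder outputs are not l2-normalized at embed time; normalization
happens inside the cosine, which is scale-invariant anyway.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, Sequence, runtime_checkable

import numpy as np


class EmbedderError(RuntimeError):
    """A backend is unavailable or rejects the request."""


@runtime_checkable
class DenseEmbedder(Protocol):
    """Contract for a dense-vector backend."""

    name: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """One row vector of length ``dim`` per input text; deterministic."""
        ...


class HashedNgramEmbedder:
    """Deterministic toy embedder over hashed character 3-grams.

    Each distinct 3-gram maps — via a cryptographic hash of (seed, gram) —
    to a fixed pseudo-random Gaussian direction; a text embeds as the
    l2-normalized sum of its 3-gram directions (with multiplicity).  At
    moderate dimension, unrelated texts land nearly orthogonal while texts
    sharing many 3-grams score high, which is the qualitative geometry a
    trained encoder provides.
    """

    def __init__(self, dim: int = 256, seed: int = 0) -> None:
        if dim < 8:
            raise ValueError(f"dim must be >= 8, got {dim}")
        self.name = f"hashed-3gram(dim={dim},seed={seed})"
        self.dim = int(dim)
        self.seed = int(seed)
        self._cache: dict[str, np.ndarray] = {}

    def _gram_vector(self, gram: str) -> np.ndarray:
        vec = self._cache.get(gram)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{gram}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[gram] = vec
        return vec

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for row, text in enumerate(texts):
            if not text:
                raise EmbedderError(f"{self.name}: cannot embed empty text")
            grams = [text[i : i + 3] for i in range(len(text) - 2)] or [text]
            for gram in grams:
                out[row] += self._gram_vector(gram)
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
        return out


def hashed_ngram_embedder(dim: int = 256, seed: int = 0) -> HashedNgramEmbedder:
    """Construct the deterministic toy embedder (see class docstring)."""
    return HashedNgramEmbedder(dim=dim, seed=seed)


class PrecomputedEmbedder:
    """File-backed embedder: a term -> vector table computed offline.

    The table format is a UTF-8 text file with header ``dim N`` followed by
    one line per term: ``term TAB space-separated floats``.  Lookup is by
    canonical term; unknown terms raise :class:`EmbedderError`.
    """

    def __init__(self, table: dict[str, np.ndarray], name: str = "precomputed") -> None:
        if not table:
            raise EmbedderError("empty vector table")
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise EmbedderError(f"inconsistent vector dimensions: {sorted(dims)}")
        self.name = name
        self.dim = dims.pop()
        self._table = {k: np.asarray(v, dtype=np.float64) for k, v in table.items()}

    @classmethod
    def from_file(cls, path) -> "PrecomputedEmbedder":
        return cls(read_vector_file(path), name=f"precomputed({path})")

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim))
        for row, text in enumerate(texts):
            vec = self._table.get(text)
            if vec is None:
                raise EmbedderError(f"{self.name}: no vector for term {text!r}")
            out[row] = vec
        return out


def embed(embedder: DenseEmbedder, texts: Sequence[str]) -> np.ndarray:
    """Batch-embed texts, validating the contract output."""
    texts = list(texts)
    if any(not t for t in texts):
        raise EmbedderError("texts must be non-empty strings")
    matrix = np.asarray(embedder.embed(texts), dtype=np.float64)
    if matrix.shape != (len(texts), embedder.dim):
        raise EmbedderError(
            f"{embedder.name}: expected shape {(len(texts), embedder.dim)}, "
            f"got {matrix.shape}"
        )
    if not np.all(np.isfinite(matrix)):
        raise EmbedderError(f"{embedder.name}: non-finite embedding values")
    return matrix


def semantic_score_matrix(
    embedder: DenseEmbedder, queries: Sequence[str], dictionary
) -> np.ndarray:
    """Semantic-similarity matrix: entry (i, j) is the cosine between query
    i's and dictionary term j's dense vectors."""
    dict_terms = [e.term for e in dictionary]
    q = embed(embedder, list(queries))
    d = embed(embedder, dict_terms)
    q_norm = np.linalg.norm(q, axis=1)
    d_norm = np.linalg.norm(d, axis=1)
    denom = np.outer(q_norm, d_norm)
    dots = q @ d.T
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0.0, dots / np.where(denom == 0.0, 1.0, denom), 0.0)


def read_vector_file(path) -> dict[str, np.ndarray]:
    """Read a term -> vector table (header ``dim N``, then term TAB floats).

    Terms must already be canonical; dimension mismatches are rejected.
    """
    from medlink.lexicon import canonicalize

    table: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise EmbedderError(f"{path}: expected header 'dim N'")
        dim, count = int(header[0]), int(header[1])
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            term, _, payload = line.partition("\t")
            if term != canonicalize(term):
                raise EmbedderError(f"{path}: line {lineno}: term not canonical: {term!r}")
            vec = np.array([float(x) for x in payload.split()])
            if len(vec) != dim:
                raise EmbedderError(
                    f"{path}: line {lineno}: expected {dim} floats, got {len(vec)}"
                )
            table[term] = vec
    if len(table) != count:
        raise EmbedderError(f"{path}: header claims {count} terms, found {len(table)}")
    return table


def write_vector_file(table: dict[str, np.ndarray], path) -> None:
    """Write a term -> vector table in the format read_vector_file expects."""
    with open(path, "w", encoding="utf-8") as handle:
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise EmbedderError(f"inconsistent vector dimensions: {sorted(dims)}")
        handle.write(f"{dims.pop()} {len(table)}\n")
        for term, vec in table.items():
            payload = " ".join(repr(float(x)) for x in vec)
            handle.write(f"{term}\t{payload}\n")
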