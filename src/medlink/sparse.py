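"""Character n-gram TF-IDF bag-of-words string similarity.

Every dictionary term is one "document".  A term is represented as a sparse
vector over the fitted n-gram vocabulary with

    tf(st, d)  = count(st in d) / total n-gram count of d
    idf(st, D) = ln(N / df(st))                      (dialect "paper")
               = ln((1 + N) / (1 + df(st))) + 1      (dialect "smoothed")
    weight     = tf · idf

and string similarity between a query and a candidate is the cosine of
their vectors.  The "paper" dialect is the literal per-document tf with
unsmoothed idf; "smoothed" matches the common vectorizer convention (under
cosine it is rank-equivalent to scikit-learn's TfidfVectorizer with a char
analyzer, since the per-document tf denominator cancels).

n-grams are taken over the full canonical string including internal spaces
(no word-boundary padding), so multiword medical terms stay comparable as
character sequences.  Combined orders (e.g. n = {2, 3}) share one
vocabulary and one tf denominator, yielding a single vector per term.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

_DIALECTS = ("paper", "smoothed")


class SparseFitError(ValueError):
    """Encoder cannot be fitted (e.g. empty dictionary)."""


def extract_ngrams(text: str, n_values: frozenset[int] | set[int]) -> Counter:
    """Multiset of character n-grams of ``text`` for each order in n_values.

    All contiguous substrings of length n, sliding by one character; a text
    shorter than n contributes nothing for that order.
    """
    for n in n_values:
        if n < 1:
            raise ValueError(f"n-gram order must be >= 1, got {n}")
    counts: Counter = Counter()
    for n in sorted(n_values):
        for i in range(len(text) - n + 1):
            counts[text[i : i + n]] += 1
    return counts


@dataclass(frozen=True)
class SparseVector:
    """l2-comparable sparse TF-IDF representation of one term.

    ``indices`` are strictly increasing column positions; ``values`` the
    matching positive weights (zero entries are absent); ``dim`` the
    vocabulary size.
    """

    indices: np.ndarray
    values: np.ndarray
    dim: int

    def norm(self) -> float:
        return float(np.sqrt(np.dot(self.values, self.values)))

    def to_dict(self) -> dict[int, float]:
        return dict(zip(self.indices.tolist(), self.values.tolist()))


class SparseEncoder:
    """Fitted character n-gram TF-IDF vocabulary with idf weights.

    Immutable after fitting; construct via :func:`fit_tfidf` or
    :meth:`load`.
    """

    def __init__(
        self,
        n_values: frozenset[int],
        vocabulary: dict[str, int],
        idf: np.ndarray,
        dialect: str,
        corpus_size: int,
    ) -> None:
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}")
        self.n_values = frozenset(n_values)
        self.vocabulary = dict(vocabulary)
        self.idf = np.asarray(idf, dtype=np.float64)
        self.idf.setflags(write=False)
        self.dialect = dialect
        self.corpus_size = int(corpus_size)
        if sorted(self.vocabulary.values()) != list(range(len(self.vocabulary))):
            raise ValueError("vocabulary indices must be a bijection onto 0..V-1")
        if len(self.idf) != len(self.vocabulary):
            raise ValueError("idf length must equal vocabulary size")

    @property
    def dim(self) -> int:
        return len(self.vocabulary)

    def save(self, path) -> None:
        """Persist as a versioned JSON archive; reload is bit-identical."""
        payload = {
            "format": "medlink-sparse-encoder",
            "version": 1,
            "n_values": sorted(self.n_values),
            "dialect": self.dialect,
            "corpus_size": self.corpus_size,
            "vocabulary": self.vocabulary,
            "idf": [value.hex() for value in self.idf],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, ensure_ascii=False)

    @classmethod
    def load(cls, path) -> "SparseEncoder":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        if payload.get("format") != "medlink-sparse-encoder":
            raise ValueError(f"{path}: not a sparse-encoder archive")
        return cls(
            n_values=frozenset(payload["n_values"]),
            vocabulary=payload["vocabulary"],
            idf=np.array([float.fromhex(v) for v in payload["idf"]]),
            dialect=payload["dialect"],
            corpus_size=payload["corpus_size"],
        )


def fit_tfidf(
    dictionary, n_values: set[int] | frozenset[int], dialect: str = "paper"
) -> SparseEncoder:
    """Fit the n-gram TF-IDF model on a term dictionary.

    Each dictionary term is one document.  The vocabulary holds every
    n-gram appearing in at least one term, indexed in first-occurrence
    order (deterministic given the dictionary order).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    terms = [e.term for e in dictionary]
    if not terms:
        raise SparseFitError("cannot fit TF-IDF on an empty dictionary")
    n_values = frozenset(n_values)
    vocabulary: dict[str, int] = {}
    df: Counter = Counter()
    for term in terms:
        grams = extract_ngrams(term, n_values)
        for gram in grams:
            if gram not in vocabulary:
                vocabulary[gram] = len(vocabulary)
            df[gram] += 1
    n_docs = len(terms)
    idf = np.empty(len(vocabulary))
    for gram, col in vocabulary.items():
        if dialect == "paper":
            idf[col] = math.log(n_docs / df[gram])
        else:
            idf[col] = math.log((1 + n_docs) / (1 + df[gram])) + 1.0
    return SparseEncoder(
        n_values=n_values,
        vocabulary=vocabulary,
        idf=idf,
        dialect=dialect,
        corpus_size=n_docs,
    )


def transform_sparse(encoder: SparseEncoder, text: str) -> SparseVector:
    """TF-IDF sparse vector of one canonical text.

    Out-of-vocabulary n-grams are ignored; entries whose weight is zero
    (zero idf under the paper dialect) are dropped.  A text with no
    in-vocabulary n-grams yields the empty vector.
    """
    grams = extract_ngrams(text, encoder.n_values)
    total = sum(grams.values())
    if total == 0:
        return SparseVector(np.empty(0, dtype=np.intp), np.empty(0), encoder.dim)
    cols: list[int] = []
    vals: list[float] = []
    for gram, count in grams.items():
        col = encoder.vocabulary.get(gram)
        if col is None:
            continue
        weight = (count / total) * encoder.idf[col]
        if weight != 0.0:
            cols.append(col)
            vals.append(weight)
    order = np.argsort(cols, kind="stable")
    return SparseVector(
        indices=np.asarray(cols, dtype=np.intp)[order],
        values=np.asarray(vals)[order],
        dim=encoder.dim,
    )


def _as_csr(encoder: SparseEncoder, texts: list[str]) -> sp.csr_matrix:
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for text in texts:
        vec = transform_sparse(encoder, text)
        indices.extend(vec.indices.tolist())
        data.extend(vec.values.tolist())
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.intp), np.asarray(indptr, dtype=np.intp)),
        shape=(len(texts), encoder.dim),
    )


def cosine_similarity(a, b) -> float:
    """Cosine of two equal-dimension vectors (sparse or dense).

    If exactly one argument is all-zero the similarity is 0 by convention;
    two all-zero vectors also score 0.
    """
    if isinstance(a, SparseVector) and isinstance(b, SparseVector):
        if a.dim != b.dim:
            raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
        na, nb = a.norm(), b.norm()
        if na == 0.0 or nb == 0.0:
            return 0.0
        da = a.to_dict()
        dot = sum(value * da.get(col, 0.0) for col, value in zip(b.indices.tolist(), b.values.tolist()))
        return dot / (na * nb)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def sparse_score_matrix(
    encoder: SparseEncoder, queries: list[str], dictionary
) -> np.ndarray:
    """String-similarity matrix: entry (i, j) is the cosine between query i
    and dictionary term j in TF-IDF space.  Rows for queries with empty
    vectors are all zero.
    """
    dict_terms = [e.term for e in dictionary]
    q_mat = _as_csr(encoder, list(queries))
    d_mat = _as_csr(encoder, dict_terms)
    q_norm = np.sqrt(np.asarray(q_mat.multiply(q_mat).sum(axis=1)).ravel())
    d_norm = np.sqrt(np.asarray(d_mat.multiply(d_mat).sum(axis=1)).ravel())
    dots = (q_mat @ d_mat.T).toarray()
    denom = np.outer(q_norm, d_norm)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0.0, dots / np.where(denom == 0.0, 1.0, denom), 0.0)
    return scores
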