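"""Score-channel fusion and the trainable linear combiner.

A query's candidates carry two similarity channels: string (character
n-gram TF-IDF cosine) and semantic (dense-vector cosine).  They can be
fused per query either by normalizing each channel and summing (z-score,
min-max, tanh schemes) or linearly,

    S = alpha * S_semantic + beta * S_string,

where (alpha, beta) are trained on labeled queries.  Training follows the
iterative candidate-mining scheme used for biomedical entity-linking
rankers: each epoch mines the top-k dictionary entries per query under the
current weights, computes the softmax over the pool's combined scores, and
maximizes the marginal probability mass that falls on candidates synonymous
with the gold concept — i.e. minimizes

    Loss = -(1/Q) * sum_i log( sum_{positives} softmax(S)_j ).

The objective has only two trainable parameters, so the optimizer is plain
full-batch gradient descent with the closed-form gradient; no stochastic
machinery is needed and runs are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SCHEMES = ("zscore", "minmax", "tanh", "linear", "string_only", "semantic_only")
NORMALIZATION_SCHEMES = ("zscore", "minmax", "tanh")

# Slope constant of the tanh normalization scheme (conventional robust form).
TANH_SLOPE = 0.01


class TrainingError(RuntimeError):
    """Training cannot proceed (e.g. no pool contains a positive)."""


@dataclass(frozen=True)
class CombinerParams:
    """Fusion scheme with its channel weights.

    For schemes ``string_only`` / ``semantic_only`` the weights are pinned
    to (0, 1) / (1, 0).  For the normalization schemes the weights apply to
    the normalized channels (default 1, 1).
    """

    scheme: str = "linear"
    alpha: float = 1.0  # semantic weight
    beta: float = 1.0  # string weight

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if self.scheme == "string_only" and (self.alpha, self.beta) != (0.0, 1.0):
            object.__setattr__(self, "alpha", 0.0)
            object.__setattr__(self, "beta", 1.0)
        if self.scheme == "semantic_only" and (self.alpha, self.beta) != (1.0, 0.0):
            object.__setattr__(self, "alpha", 1.0)
            object.__setattr__(self, "beta", 0.0)

    def save(self, path, loss_trace: list[float] | None = None, **extra) -> None:
        """Persist as a small JSON document (scheme, weights, optional trace)."""
        import json

        payload = {"scheme": self.scheme, "alpha": self.alpha, "beta": self.beta}
        if loss_trace is not None:
            payload["loss_trace"] = list(map(float, loss_trace))
        payload.update(extra)
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)

    @classmethod
    def load(cls, path) -> "CombinerParams":
        import json

        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            scheme=payload["scheme"],
            alpha=payload["alpha"],
            beta=payload["beta"],
        )


@dataclass(frozen=True)
class ScoredCandidate:
    """One dictionary entry scored against one query."""

    concept_id: str
    term: str
    s_string: float
    s_semantic: float
    s_combined: float
    is_positive: bool | None = None


@dataclass(frozen=True)
class CandidatePool:
    """Ranked top-k candidates for one query, channels kept unfused."""

    query_id: str
    candidates: tuple[ScoredCandidate, ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.candidates) > self.k:
            raise ValueError("pool larger than k")

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the linear-combiner trainer.

    k is the mined pool size (the top-k recommendation set); the weights
    start at (init_alpha, init_beta) and take ``epochs`` full-batch
    gradient steps of size ``learning_rate``; pools are re-mined under the
    current weights every ``remine_every`` epochs.
    """

    k: int = 20
    epochs: int = 100
    learning_rate: float = 0.5
    seed: int = 0
    init_alpha: float = 1.0
    init_beta: float = 1.0
    remine_every: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.remine_every < 1:
            raise ValueError("remine_every must be >= 1")


def normalize_channel(scores, scheme: str) -> np.ndarray:
    """Normalize one per-query score channel.

    zscore: (s - mean) / sd with population sd; minmax: (s - min) /
    (max - min); tanh: 0.5 * (tanh(0.01 * (s - mean)/sd) + 1).  Degenerate
    pools (zero spread) map to all-0 for zscore and all-0.5 for
    minmax/tanh.  All three maps are monotone non-decreasing, so within-
    pool score order is preserved.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 1:
        raise ValueError("scores must have length >= 1")
    if scheme == "zscore":
        sd = scores.std()
        if sd == 0.0:
            return np.zeros_like(scores)
        return (scores - scores.mean()) / sd
    if scheme == "minmax":
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            return np.full_like(scores, 0.5)
        return (scores - lo) / (hi - lo)
    if scheme == "tanh":
        sd = scores.std()
        if sd == 0.0:
            return np.full_like(scores, 0.5)
        return 0.5 * (np.tanh(TANH_SLOPE * (scores - scores.mean()) / sd) + 1.0)
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def combine_linear(s_semantic: float, s_string: float, params: CombinerParams) -> float:
    """Weighted sum alpha * s_semantic + beta * s_string."""
    if params.scheme not in ("linear", "string_only", "semantic_only"):
        raise ValueError(f"combine_linear does not apply to scheme {params.scheme!r}")
    if not (math.isfinite(s_semantic) and math.isfinite(s_string)):
        raise ValueError("scores must be finite")
    return params.alpha * s_semantic + params.beta * s_string


def _top_k_stable(combined: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries; ties broken by position (stable)."""
    order = np.argsort(-combined, kind="stable")
    return order[:k]


def mine_candidates(
    string_scores,
    semantic_scores,
    params: CombinerParams,
    k: int,
    dictionary,
    gold: frozenset[str] | set[str] | None = None,
    query_id: str = "",
) -> CandidatePool:
    """Top-k dictionary entries under the current combined score.

    Per-channel scores are retained unfused on each candidate so the
    marginal loss can re-evaluate the pool under different weights.
    ``is_positive`` is filled from ``gold`` when labels are given.  If k
    exceeds the dictionary size the pool is truncated with a warning.
    """
    string_scores = np.asarray(string_scores, dtype=np.float64)
    semantic_scores = np.asarray(semantic_scores, dtype=np.float64)
    n = len(dictionary)
    if string_scores.shape != (n,) or semantic_scores.shape != (n,):
        raise ValueError("score rows must align with the dictionary")
    if k > n:
        logger.warning("pool size %d exceeds dictionary size %d; truncating", k, n)
        k = n
    combined = params.alpha * semantic_scores + params.beta * string_scores
    top = _top_k_stable(combined, k)
    candidates = []
    for idx in top:
        entry = dictionary[int(idx)]
        candidates.append(
            ScoredCandidate(
                concept_id=entry.concept_id,
                term=entry.term,
                s_string=float(string_scores[idx]),
                s_semantic=float(semantic_scores[idx]),
                s_combined=float(combined[idx]),
                is_positive=None if gold is None else entry.concept_id in gold,
            )
        )
    return CandidatePool(query_id=query_id, candidates=tuple(candidates), k=k)


def _pool_channels(pool: CandidatePool):
    sem = np.array([c.s_semantic for c in pool.candidates])
    stg = np.array([c.s_string for c in pool.candidates])
    pos = np.array([bool(c.is_positive) for c in pool.candidates])
    if any(c.is_positive is None for c in pool.candidates):
        raise ValueError("pool candidates lack is_positive labels")
    return sem, stg, pos


def marginal_probability(pool: CandidatePool, params: CombinerParams) -> float:
    """Softmax mass on the positive candidates of a pool.

    P(n_i | q) = exp(S_i) / sum_j exp(S_j) over the pool with
    S = alpha * s_semantic + beta * s_string, computed max-shifted for
    stability; returns the sum of P over positives.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    sem, stg, pos = _pool_channels(pool)
    if not pos.any():
        raise TrainingError(
            f"pool {pool.query_id!r} has no positive candidate (upstream filter failed)"
        )
    scores = params.alpha * sem + params.beta * stg
    scores = scores - scores.max()
    weights = np.exp(scores)
    return float(weights[pos].sum() / weights.sum())


def marginal_loss(pools, params: CombinerParams) -> float:
    """Negative mean log marginal probability over a pool collection."""
    pools = list(pools)
    if not pools:
        raise ValueError("empty pool collection")
    total = 0.0
    for pool in pools:
        total += math.log(marginal_probability(pool, params))
    return -total / len(pools)


def marginal_loss_gradient(pools, params: CombinerParams) -> tuple[float, float]:
    """Closed-form gradient of the marginal loss w.r.t. (alpha, beta).

    For one pool with softmax p and positive set P:
      d(-log P')/d alpha = E_all[s_semantic] - E_pos[s_semantic]
    where E_pos is the expectation under p restricted (renormalized) to P;
    likewise for beta with the string channel.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("empty pool collection")
    g_alpha = 0.0
    g_beta = 0.0
    for pool in pools:
        sem, stg, pos = _pool_channels(pool)
        if not pos.any():
            raise TrainingError(f"pool {pool.query_id!r} has no positive candidate")
        scores = params.alpha * sem + params.beta * stg
        scores -= scores.max()
        w = np.exp(scores)
        p = w / w.sum()
        p_pos = p[pos].sum()
        g_alpha += float(p @ sem - (p[pos] @ sem[pos]) / p_pos)
        g_beta += float(p @ stg - (p[pos] @ stg[pos]) / p_pos)
    q = len(pools)
    return g_alpha / q, g_beta / q


def train_combiner(
    queries,
    string_matrix,
    semantic_matrix,
    dictionary,
    config: TrainConfig = TrainConfig(),
) -> tuple[CombinerParams, list[float]]:
    """Train (alpha, beta) by gradient descent on the marginal loss.

    Each epoch (re-)mines top-k pools per query under the current weights,
    drops pools whose top-k contains no gold concept (count logged; their
    loss would be log 0), and takes one full-batch step.  Returns the final
    params and the per-epoch loss trace (loss evaluated on that epoch's
    pools before the step).

    The run is exactly reproducible: the only nondeterminism a seed could
    control is absent (full-batch updates, stable tie-breaking).
    """
    queries = list(queries)
    string_matrix = np.asarray(string_matrix, dtype=np.float64)
    semantic_matrix = np.asarray(semantic_matrix, dtype=np.float64)
    n = len(dictionary)
    if string_matrix.shape != (len(queries), n) or semantic_matrix.shape != (len(queries), n):
        raise ValueError("score matrices must be (n_queries, n_entries)")
    for q in queries:
        if not q.gold_concept_ids:
            raise ValueError(f"training query {q.query_id!r} has no gold labels")
    concept_ids = np.array(dictionary.concept_ids)
    gold_masks = np.stack(
        [np.isin(concept_ids, sorted(q.gold_concept_ids)) for q in queries]
    )
    if not gold_masks.any(axis=1).all():
        missing = [q.query_id for q, m in zip(queries, gold_masks) if not m.any()]
        raise ValueError(f"gold ids absent from dictionary for queries: {missing[:5]}")

    alpha = float(config.init_alpha)
    beta = float(config.init_beta)
    k = min(config.k, n)
    history: list[float] = []
    pool_idx = pos_mask = keep = None
    for epoch in range(config.epochs):
        if epoch % config.remine_every == 0 or pool_idx is None:
            combined = alpha * semantic_matrix + beta * string_matrix
            # stable top-k per row: ties resolved by dictionary position
            order = np.argsort(-combined, axis=1, kind="stable")
            pool_idx = order[:, :k]
            pos_mask = np.take_along_axis(gold_masks, pool_idx, axis=1)
            keep = pos_mask.any(axis=1)
            dropped = int((~keep).sum())
            if dropped:
                logger.info(
                    "epoch %d: dropped %d/%d pools without a positive",
                    epoch, dropped, len(queries),
                )
            if not keep.any():
                raise TrainingError(
                    "no pool contains a positive candidate; k too small or "
                    "labels inconsistent with the dictionary"
                )
        rows = np.arange(len(queries))[keep]
        sem = semantic_matrix[rows[:, None], pool_idx[keep]]
        stg = string_matrix[rows[:, None], pool_idx[keep]]
        pos = pos_mask[keep]
        scores = alpha * sem + beta * stg
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        p = w / w.sum(axis=1, keepdims=True)
        p_pos = np.where(pos, p, 0.0).sum(axis=1)
        history.append(float(-np.log(p_pos).mean()))
        e_all_sem = (p * sem).sum(axis=1)
        e_pos_sem = np.where(pos, p * sem, 0.0).sum(axis=1) / p_pos
        e_all_stg = (p * stg).sum(axis=1)
        e_pos_stg = np.where(pos, p * stg, 0.0).sum(axis=1) / p_pos
        g_alpha = float((e_all_sem - e_pos_sem).mean())
        g_beta = float((e_all_stg - e_pos_stg).mean())
        alpha -= config.learning_rate * g_alpha
        beta -= config.learning_rate * g_beta
    return CombinerParams(scheme="linear", alpha=alpha, beta=beta), history
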