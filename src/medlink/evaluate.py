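"""End-to-end mapping pipeline and its evaluation harness.

``map_entities`` runs one strategy over a query set: build each query's
variant set (translations or the surface alone), score every variant
against the dictionary on both channels, take the per-channel maximum over
variants, fuse per the chosen scheme, and rank.  Accuracy is Acc@n — the
percentage of queries whose gold concept appears among the top n distinct
concepts — and paired strategies are compared with McNemar's test on their
discordant hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from medlink.fusion import (
    CombinerParams,
    NORMALIZATION_SCHEMES,
    ScoredCandidate,
    normalize_channel,
)
from medlink.sparse import sparse_score_matrix
from medlink.dense import semantic_score_matrix
from medlink.translation import unify_translations, TranslationError

logger = logging.getLogger(__name__)

#: number of discordant pairs below which McNemar's test is exact binomial
MCNEMAR_EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class MappingResult:
    """Ranked candidates for one query plus the rank of the first gold hit."""

    query_id: str
    ranked: tuple[ScoredCandidate, ...]
    hit_rank: int | None
    gold_concept_ids: frozenset[str] = frozenset()

    def hit_within(self, n: int) -> bool:
        return self.hit_rank is not None and self.hit_rank <= n


@dataclass(frozen=True)
class EvalResult:
    """Acc@n accuracies (percentages) with per-query hit ranks."""

    N: int
    acc: dict[int, float]
    per_query_hit_ranks: tuple[int | None, ...]


@dataclass(frozen=True)
class McNemarResult:
    """Discordant counts and significance of a paired strategy comparison."""

    b: int  # correct under A only
    c: int  # correct under B only
    statistic: float | None
    p_value: float
    method: str  # exact_binomial | chi2_corrected


def channel_matrices(
    queries,
    dictionary,
    encoder,
    embedder,
    providers=None,
):
    """Per-query per-entry (string, semantic) score rows, max over variants.

    Each query contributes the texts of its variant set — translations
    produced by ``providers`` when given, else the variants already on the
    query, else the bare surface — and each channel's score against a
    dictionary entry is the maximum over those texts.  Taking the maximum
    per channel before fusion means adding variants can never lower a
    candidate's score.
    """
    queries = list(queries)
    texts: list[str] = []
    slices: list[tuple[int, int]] = []
    for query in queries:
        if providers:
            try:
                variants = unify_translations(query.surface, providers).texts()
            except TranslationError:
                variants = []
            if not variants:
                logger.warning(
                    "query %s: no translation variants; falling back to surface",
                    query.query_id,
                )
                variants = [query.surface]
        else:
            variants = query.variant_texts()
        start = len(texts)
        texts.extend(variants)
        slices.append((start, len(texts)))
    string_all = sparse_score_matrix(encoder, texts, dictionary)
    semantic_all = semantic_score_matrix(embedder, texts, dictionary)
    n = len(dictionary)
    string_matrix = np.empty((len(queries), n))
    semantic_matrix = np.empty((len(queries), n))
    for i, (lo, hi) in enumerate(slices):
        string_matrix[i] = string_all[lo:hi].max(axis=0)
        semantic_matrix[i] = semantic_all[lo:hi].max(axis=0)
    return string_matrix, semantic_matrix


def fuse_scores(
    string_row: np.ndarray, semantic_row: np.ndarray, params: CombinerParams
) -> np.ndarray:
    """Combined score row under one fusion scheme.

    Normalization schemes operate per query over the candidate set (this
    row), then weight the channels; linear and the single-channel schemes
    weight the raw cosines directly.
    """
    if params.scheme in NORMALIZATION_SCHEMES:
        sem = normalize_channel(semantic_row, params.scheme)
        stg = normalize_channel(string_row, params.scheme)
        return params.alpha * sem + params.beta * stg
    return params.alpha * semantic_row + params.beta * string_row


def _rank_row(
    string_row: np.ndarray,
    semantic_row: np.ndarray,
    params: CombinerParams,
    dictionary,
    n_max: int,
    gold: frozenset[str],
    query_id: str,
    dedup_concepts: bool = True,
) -> MappingResult:
    combined = fuse_scores(string_row, semantic_row, params)
    order = np.argsort(-combined, kind="stable")
    ranked: list[ScoredCandidate] = []
    hit_rank: int | None = None
    seen_concepts: set[str] = set()
    rank = 0
    for idx in order:
        entry = dictionary[int(idx)]
        if dedup_concepts:
            if entry.concept_id in seen_concepts:
                continue
            seen_concepts.add(entry.concept_id)
        rank += 1
        ranked.append(
            ScoredCandidate(
                concept_id=entry.concept_id,
                term=entry.term,
                s_string=float(string_row[idx]),
                s_semantic=float(semantic_row[idx]),
                s_combined=float(combined[idx]),
                is_positive=(entry.concept_id in gold) if gold else None,
            )
        )
        if hit_rank is None and gold and entry.concept_id in gold:
            hit_rank = rank
        if rank >= n_max:
            # a gold concept outside the retrieved top-n_max is a miss
            break
    return MappingResult(
        query_id=query_id,
        ranked=tuple(ranked),
        hit_rank=hit_rank,
        gold_concept_ids=gold,
    )


def map_entities(
    queries,
    dictionary,
    encoder,
    embedder,
    params: CombinerParams,
    providers=None,
    n_max: int = 10,
    dedup_concepts: bool = True,
) -> list[MappingResult]:
    """Rank dictionary concepts for each query under one strategy.

    Duplicate concept ids in the ranking (same concept, different terms)
    are collapsed to the best-scoring term before rank counting, so ``n``
    in Acc@n refers to distinct concepts; pass ``dedup_concepts=False`` to
    count raw term rows instead.  Deterministic end-to-end: ties break by
    dictionary position.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    queries = list(queries)
    string_matrix, semantic_matrix = channel_matrices(
        queries, dictionary, encoder, embedder, providers
    )
    return [
        _rank_row(
            string_matrix[i],
            semantic_matrix[i],
            params,
            dictionary,
            n_max,
            frozenset(query.gold_concept_ids),
            query.query_id,
            dedup_concepts,
        )
        for i, query in enumerate(queries)
    ]


def acc_at_n(results, n: int) -> float:
    """Top-n accuracy as a percentage: 100 * |{hit_rank <= n}| / N."""
    results = list(results)
    if not results:
        raise ValueError("empty result collection")
    if n < 1:
        raise ValueError("n must be >= 1")
    hits = sum(1 for r in results if r.hit_within(n))
    return 100.0 * hits / len(results)


def evaluate_results(results, ns=(1, 5, 10)) -> EvalResult:
    """Acc@n for each cutoff plus the per-query hit ranks."""
    results = list(results)
    return EvalResult(
        N=len(results),
        acc={n: acc_at_n(results, n) for n in ns},
        per_query_hit_ranks=tuple(r.hit_rank for r in results),
    )


def mcnemar_test(hits_a, hits_b) -> McNemarResult:
    """McNemar's paired test on two aligned correctness vectors.

    b counts queries correct under A only, c under B only.  With fewer
    than 25 discordant pairs the p-value is the exact two-sided binomial
    test of b against Binomial(b + c, 1/2); otherwise the continuity-
    corrected chi-square (|b - c| - 1)^2 / (b + c) with 1 df.  No
    discordance yields p = 1.
    """
    hits_a = np.asarray(hits_a, dtype=bool)
    hits_b = np.asarray(hits_b, dtype=bool)
    if hits_a.shape != hits_b.shape:
        raise ValueError("hit vectors must be aligned (equal length)")
    b = int(np.sum(hits_a & ~hits_b))
    c = int(np.sum(~hits_a & hits_b))
    if b + c == 0:
        return McNemarResult(b=b, c=c, statistic=None, p_value=1.0, method="exact_binomial")
    if b + c < MCNEMAR_EXACT_THRESHOLD:
        p = stats.binomtest(b, n=b + c, p=0.5, alternative="two-sided").pvalue
        return McNemarResult(b=b, c=c, statistic=None, p_value=float(p), method="exact_binomial")
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    p = stats.chi2.sf(statistic, df=1)
    return McNemarResult(
        b=b, c=c, statistic=float(statistic), p_value=float(p), method="chi2_corrected"
    )


def strategy_params(strategy_id: str, alpha: float = 1.0, beta: float = 1.0) -> CombinerParams:
    """CombinerParams for a strategy id as used by the report and the CLI."""
    mapping = {
        "string_tfidf": CombinerParams(scheme="string_only", alpha=0.0, beta=1.0),
        "semantic": CombinerParams(scheme="semantic_only", alpha=1.0, beta=0.0),
        "zscore": CombinerParams(scheme="zscore", alpha=alpha, beta=beta),
        "minmax": CombinerParams(scheme="minmax", alpha=alpha, beta=beta),
        "tanh": CombinerParams(scheme="tanh", alpha=alpha, beta=beta),
        "linear": CombinerParams(scheme="linear", alpha=alpha, beta=beta),
    }
    if strategy_id not in mapping:
        raise ValueError(f"unknown strategy id {strategy_id!r}")
    return mapping[strategy_id]


def strategy_report(
    queries,
    dictionary,
    encoder,
    embedder,
    strategies: dict[str, CombinerParams],
    baseline: str,
    providers=None,
    ns=(1, 5, 10),
    n_max: int | None = None,
    path=None,
):
    """Acc@n table for several strategies with McNemar p against a baseline.

    Returns a pandas DataFrame (one row per strategy, Acc@n columns and the
    Acc@1 McNemar p-value against ``baseline``); written as a
    commented-header TSV when ``path`` is given.
    """
    import pandas as pd

    if not strategies:
        raise ValueError("at least one strategy is required")
    if baseline not in strategies:
        raise ValueError(f"baseline {baseline!r} not among strategies")
    n_max = n_max or max(ns)
    all_results = {
        name: map_entities(
            queries, dictionary, encoder, embedder, params, providers, n_max=n_max
        )
        for name, params in strategies.items()
    }
    base_hits = np.array([r.hit_within(1) for r in all_results[baseline]])
    rows = []
    for name, results in all_results.items():
        hits = np.array([r.hit_within(1) for r in results])
        test = mcnemar_test(hits, base_hits)
        row = {"strategy": name}
        for n in ns:
            row[f"acc@{n}"] = acc_at_n(results, n)
        row["mcnemar_p_vs_baseline"] = 1.0 if name == baseline else test.p_value
        rows.append(row)
    frame = pd.DataFrame(rows)
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"# medlink strategy report; baseline={baseline}; N={len(list(queries))}\n")
            frame.to_csv(handle, sep="\t", index=False, float_format="%.6g")
    return frame
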