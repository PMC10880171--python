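"""Seed-reproducible synthetic benchmarks for the mapping pipeline.

Real evaluations of this pipeline need a licensed reference vocabulary,
commercial translation engines, and a pretrained encoder.  The generator
emulates the computational structure of that setting without any of them:

* a synonym-rich concept dictionary — each concept owns a random base
  word-string and several surface variants produced by seeded edit
  operations (character substitution, token swap, affix);
* noisy query variants — each query picks a gold concept and presents
  ``variant_count`` independent perturbations of one of its synonyms,
  standing in for round-trip translation variants of a source-language
  term;
* concept-latent dense vectors — each concept gets one latent unit vector;
  every term and variant embeds as that latent plus Gaussian noise,
  emulating an encoder in which terms of one concept form a packed
  cluster.

``channel_mode`` controls which score channel is informative: ``both``
(default), ``string_only`` (query-side vectors are random, so only string
similarity carries signal), or ``semantic_only`` (variants are random
strings, so only the dense channel carries signal).  The single-channel
benchmarks are what make the combiner's parameter-recovery tests
meaningful.

All randomness flows from ``config.seed`` through named generators (one
per stage), so regeneration from the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

from medlink.dense import PrecomputedEmbedder, write_vector_file
from medlink.lexicon import (
    ConceptEntry,
    Query,
    TermDictionary,
    write_concept_dictionary,
    write_queries,
)
from medlink.translation import TranslationSet

_ALPHABET = "abcdefghijklmnopqrst"
_CHANNEL_MODES = ("both", "string_only", "semantic_only")


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark shape and noise levels.

    Defaults give a desk-scale benchmark: 500 concepts x 3 synonyms,
    400 labeled queries with 2 variants each, moderate string noise
    (15% edit rate) and semantic noise (sd 0.3 around the concept latent
    at dimension 64) — enough signal in each channel for stable accuracy
    estimates in seconds-scale runs.
    """

    n_concepts: int = 500
    synonyms_per_concept: int = 3
    n_queries: int = 400
    string_noise: float = 0.15
    variant_count: int = 2
    semantic_noise: float = 0.3
    channel_mode: str = "both"
    dim: int = 64
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValueError("n_concepts must be >= 2")
        if self.synonyms_per_concept < 1:
            raise ValueError("synonyms_per_concept must be >= 1")
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")
        if not 0.0 <= self.string_noise <= 1.0:
            raise ValueError("string_noise must be in [0, 1]")
        if self.variant_count < 1:
            raise ValueError("variant_count must be >= 1")
        if self.semantic_noise < 0.0:
            raise ValueError("semantic_noise must be >= 0")
        if self.channel_mode not in _CHANNEL_MODES:
            raise ValueError(f"channel_mode must be one of {_CHANNEL_MODES}")
        if self.dim < 8:
            raise ValueError("dim must be >= 8")


def _stage_rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_word(rng: np.random.Generator, lo: int = 4, hi: int = 8) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(_ALPHABET[int(i)] for i in rng.integers(0, len(_ALPHABET), length))


def _random_term(rng: np.random.Generator) -> str:
    n_words = int(rng.integers(2, 5))
    return " ".join(_random_word(rng) for _ in range(n_words))


def _perturb(text: str, rate: float, rng: np.random.Generator) -> str:
    """One noisy alias: per-character substitution, token swap, affix."""
    words = [list(w) for w in text.split()]
    for chars in words:
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
    words = ["".join(chars) for chars in words]
    if len(words) >= 2 and rng.random() < rate:
        i = int(rng.integers(len(words) - 1))
        words[i], words[i + 1] = words[i + 1], words[i]
    if rng.random() < rate:
        affix = _random_word(rng, 2, 3)
        i = int(rng.integers(len(words)))
        words[i] = affix + words[i] if rng.random() < 0.5 else words[i] + affix
    return " ".join(words)


def generate_dictionary(config: SyntheticConfig) -> TermDictionary:
    """Synonym-rich concept dictionary.

    Each concept id ``C<i>`` gets ``synonyms_per_concept`` surface variants
    of its base string perturbed at rate ``string_noise`` (rate 0 collapses
    all synonyms onto the base).  Duplicate (concept, term) pairs collapse,
    so the dictionary may be smaller than concepts x synonyms.
    """
    rng = _stage_rng(config, 0)
    dictionary = TermDictionary()
    for i in range(config.n_concepts):
        concept_id = f"C{i:05d}"
        base = _random_term(rng)
        for _ in range(config.synonyms_per_concept):
            term = _perturb(base, config.string_noise, rng)
            dictionary.add(
                ConceptEntry(
                    concept_id=concept_id,
                    term=term,
                    language="und",
                    source="synthetic",
                    semantic_group="Disorders",
                )
            )
    return dictionary


def generate_queries(dictionary: TermDictionary, config: SyntheticConfig) -> list[Query]:
    """Labeled queries with noisy "translation variants".

    Each query picks a concept uniformly and perturbs one of its synonyms
    ``variant_count`` times at rate ``string_noise``.  Under
    ``semantic_only`` the variants are replaced with random strings (string
    channel uninformative); under ``string_only`` variants are kept
    textually distinct from every dictionary term so that the random
    query-side vectors assigned later cannot collide with dictionary
    vectors through a shared term key.
    """
    rng = _stage_rng(config, 1)
    concept_ids = list(dict.fromkeys(dictionary.concept_ids))
    queries: list[Query] = []
    for j in range(config.n_queries):
        concept_id = concept_ids[int(rng.integers(len(concept_ids)))]
        positions = dictionary.by_concept[concept_id]
        synonym = dictionary[positions[int(rng.integers(len(positions)))]].term
        variants: list[str] = []
        for _ in range(config.variant_count):
            if config.channel_mode == "semantic_only":
                variant = _random_term(rng)
            else:
                variant = _perturb(synonym, config.string_noise, rng)
                if config.channel_mode == "string_only":
                    # keep variant text off the dictionary key space
                    attempts = 0
                    while variant in dictionary.by_term:
                        variant = _perturb(
                            synonym, max(config.string_noise, 0.05), rng
                        )
                        attempts += 1
                        if attempts >= 50:
                            variant = variant + " " + _random_word(rng, 2, 3)
            if variant not in variants:
                variants.append(variant)
        queries.append(
            Query(
                query_id=f"q{j:04d}",
                surface=synonym,
                language="und",
                gold_concept_ids=frozenset({concept_id}),
                translations=TranslationSet(
                    variants=[(v, frozenset({"synthetic"})) for v in variants]
                ),
            )
        )
    return queries


def generate_dense_vectors(
    dictionary: TermDictionary, queries: list[Query], config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Term -> unit-vector table for dictionary terms and query variants.

    One latent unit vector per concept; every term of the concept embeds as
    latent + Gaussian(0, semantic_noise) noise, l2-normalized.  Under
    ``string_only`` query-side vectors are fresh random unit vectors
    instead, making the semantic channel pure noise.
    """
    rng = _stage_rng(config, 2)
    concept_ids = list(dict.fromkeys(dictionary.concept_ids))
    latents: dict[str, np.ndarray] = {}
    for concept_id in concept_ids:
        vec = rng.standard_normal(config.dim)
        latents[concept_id] = vec / np.linalg.norm(vec)

    def noisy(latent: np.ndarray) -> np.ndarray:
        vec = latent + rng.normal(0.0, config.semantic_noise, config.dim)
        return vec / np.linalg.norm(vec)

    table: dict[str, np.ndarray] = {}
    for entry in dictionary:
        if entry.term not in table:
            table[entry.term] = noisy(latents[entry.concept_id])
    for query in queries:
        gold = next(iter(query.gold_concept_ids))
        for text in query.variant_texts():
            if text in table:
                continue
            if config.channel_mode == "string_only":
                vec = rng.standard_normal(config.dim)
                table[text] = vec / np.linalg.norm(vec)
            else:
                table[text] = noisy(latents[gold])
    return table


@dataclass
class SyntheticBenchmark:
    """A generated benchmark bundle: dictionary, queries, vectors, config."""

    dictionary: TermDictionary
    queries: list[Query]
    dense_vectors: dict[str, np.ndarray]
    config: SyntheticConfig

    def embedder(self) -> PrecomputedEmbedder:
        return PrecomputedEmbedder(self.dense_vectors, name="synthetic-latent")

    def write(self, directory) -> None:
        """Write dictionary TSV, queries JSONL, vector file, config echo."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_concept_dictionary(self.dictionary, directory / "dictionary.tsv")
        write_queries(self.queries, directory / "queries.jsonl")
        write_vector_file(self.dense_vectors, directory / "vectors.txt")
        with open(directory / "config.json", "w", encoding="utf-8") as handle:
            json.dump(self.config.__dict__, handle, indent=1)


def generate_benchmark(config: SyntheticConfig | None = None, **overrides) -> SyntheticBenchmark:
    """Generate the full benchmark bundle from one config."""
    config = replace(config or SyntheticConfig(), **overrides)
    dictionary = generate_dictionary(config)
    queries = generate_queries(dictionary, config)
    vectors = generate_dense_vectors(dictionary, queries, config)
    return SyntheticBenchmark(
        dictionary=dictionary, queries=queries, dense_vectors=vectors, config=config
    )
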