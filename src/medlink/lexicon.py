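"""Concept dictionaries and query sets: reading, validation, canonicalization.

The reference vocabulary is a flat list of (concept_id, term) pairs, in the
style of the UMLS MRCONSO table, where one concept id (CUI) may own many
surface terms across source vocabularies.  All text entering the pipeline —
dictionary terms, query surfaces, translation variants — passes through one
canonicalization function so that the string and semantic score channels see
identical text.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")

# MRCONSO.RRF column positions (0-based) consulted by the reader.
_MRCONSO_CUI = 0
_MRCONSO_LAT = 1
_MRCONSO_SAB = 11
_MRCONSO_STR = 14
_MRCONSO_SUPPRESS = 16
_MRCONSO_MIN_COLS = 15


class LexiconError(ValueError):
    """Malformed dictionary or query input."""


def canonicalize(text: str) -> str:
    """Canonical form of a surface string.

    Lowercase, unicode NFKC, internal whitespace runs collapsed to single
    spaces, stripped.  Idempotent; the empty string maps to itself (callers
    that require non-empty text reject empties).
    """
    text = unicodedata.normalize("NFKC", text)
    text = text.lower()
    text = _WS_RE.sub(" ", text).strip()
    return text


@dataclass(frozen=True)
class ConceptEntry:
    """One (concept id, term) row of the reference vocabulary."""

    concept_id: str
    term: str
    language: str = "und"
    source: str = ""
    semantic_group: str = ""

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise LexiconError("concept_id must be non-empty")
        if not self.term:
            raise LexiconError("term must be non-empty after canonicalization")


class TermDictionary:
    """Ordered collection of concept entries with lookup indexes.

    Iteration order is input order; (concept_id, term) pairs are unique.
    """

    def __init__(self, entries: list[ConceptEntry] | None = None) -> None:
        self.entries: list[ConceptEntry] = []
        self.by_concept: dict[str, list[int]] = {}
        self.by_term: dict[str, list[int]] = {}
        self._pairs: set[tuple[str, str]] = set()
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: ConceptEntry) -> bool:
        """Append an entry; duplicate (concept_id, term) pairs are ignored.

        Returns True if the entry was added.
        """
        key = (entry.concept_id, entry.term)
        if key in self._pairs:
            return False
        pos = len(self.entries)
        self.entries.append(entry)
        self._pairs.add(key)
        self.by_concept.setdefault(entry.concept_id, []).append(pos)
        self.by_term.setdefault(entry.term, []).append(pos)
        return True

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, pos: int) -> ConceptEntry:
        return self.entries[pos]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermDictionary):
            return NotImplemented
        return self.entries == other.entries

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.entries]

    @property
    def concept_ids(self) -> list[str]:
        return [e.concept_id for e in self.entries]


@dataclass
class Query:
    """A surface term to normalize, with optional gold labels and variants.

    ``gold_concept_ids`` is a set because one term may legitimately map to
    several concept ids; a prediction is correct if it hits any of them.
    An empty gold set marks an unlabeled (inference-mode) query.
    """

    query_id: str
    surface: str
    language: str = "und"
    gold_concept_ids: frozenset[str] = frozenset()
    translations: "TranslationSetLike | None" = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise LexiconError(f"query {self.query_id!r}: empty surface")
        self.gold_concept_ids = frozenset(self.gold_concept_ids)

    def variant_texts(self) -> list[str]:
        """Texts to score: translation variants if present, else the surface."""
        if self.translations is not None and self.translations.texts():
            return self.translations.texts()
        return [self.surface]


class TranslationSetLike:
    """Minimal protocol for a variant set (see medlink.translation)."""

    def texts(self) -> list[str]:  # pragma: no cover - interface stub
        raise NotImplementedError


def read_concept_dictionary(
    path,
    format: str = "tsv",
    semantic_group_filter: set[str] | None = None,
    keep_suppressed: bool = True,
) -> TermDictionary:
    """Read a concept dictionary from an MRCONSO.RRF or 2-column TSV file.

    Parameters
    ----------
    path
        UTF-8 text file.
    format
        ``"mrconso"``: pipe-delimited rows with the CUI in column 0 and the
        surface string in column 14 (the MRCONSO.RRF layout); ``"tsv"``:
        ``concept_id TAB term`` with optional third/fourth columns for the
        semantic group and language.
    semantic_group_filter
        If given, keep only entries whose semantic-group tag is in the set
        (e.g. ``{"Disorders"}`` to restrict candidates to one group).
    keep_suppressed
        MRCONSO only: if False, drop rows whose SUPPRESS flag is "O" or "E".

    Rows whose term canonicalizes to the empty string are skipped (count
    logged); duplicate (concept_id, term) pairs collapse to the first row.
    """
    if format not in ("mrconso", "tsv"):
        raise LexiconError(f"unknown dictionary format {format!r}")
    dictionary = TermDictionary()
    skipped_empty = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if format == "mrconso":
                cols = line.split("|")
                if len(cols) < _MRCONSO_MIN_COLS:
                    raise LexiconError(
                        f"{path}: line {lineno}: expected >= {_MRCONSO_MIN_COLS} "
                        f"pipe-delimited columns, got {len(cols)}"
                    )
                suppress = cols[_MRCONSO_SUPPRESS] if len(cols) > _MRCONSO_SUPPRESS else ""
                if not keep_suppressed and suppress in ("O", "E"):
                    continue
                concept_id = cols[_MRCONSO_CUI].strip()
                term = canonicalize(cols[_MRCONSO_STR])
                language = cols[_MRCONSO_LAT].strip().lower() or "und"
                source = cols[_MRCONSO_SAB].strip()
                group = ""
            else:
                cols = line.split("\t")
                if len(cols) < 2:
                    raise LexiconError(
                        f"{path}: line {lineno}: expected >= 2 tab-delimited "
                        f"columns, got {len(cols)}"
                    )
                concept_id = cols[0].strip()
                term = canonicalize(cols[1])
                group = cols[2].strip() if len(cols) > 2 else ""
                language = cols[3].strip().lower() if len(cols) > 3 else "und"
                source = ""
            if not term:
                skipped_empty += 1
                continue
            if not concept_id:
                raise LexiconError(f"{path}: line {lineno}: empty concept id")
            if semantic_group_filter is not None and group not in semantic_group_filter:
                continue
            dictionary.add(
                ConceptEntry(
                    concept_id=concept_id,
                    term=term,
                    language=language,
                    source=source,
                    semantic_group=group,
                )
            )
    if skipped_empty:
        logger.info("skipped %d rows with empty terms", skipped_empty)
    return dictionary


def write_concept_dictionary(dictionary: TermDictionary, path) -> None:
    """Write a dictionary as ``concept_id TAB term TAB group TAB language``."""
    with open(path, "w", encoding="utf-8") as handle:
        for entry in dictionary:
            handle.write(
                f"{entry.concept_id}\t{entry.term}\t{entry.semantic_group}\t{entry.language}\n"
            )


def read_queries(path, format: str = "jsonl") -> list[Query]:
    """Read a query set from a TSV or JSON-lines file.

    TSV columns: ``query_id TAB surface [TAB semicolon-joined gold ids]``.
    JSONL records: ``{"query_id", "surface", "language"?, "gold_concept_ids"?,
    "translations"?}`` where translations is a list of variant strings.

    Surfaces and variants are canonicalized; variants de-duplicated in first
    occurrence order.  Duplicate query ids raise a validation error.
    """
    from medlink.translation import TranslationSet

    if format not in ("tsv", "jsonl"):
        raise LexiconError(f"unknown query format {format!r}")
    queries: list[Query] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if format == "tsv":
                cols = line.split("\t")
                if len(cols) < 2:
                    raise LexiconError(
                        f"{path}: line {lineno}: expected >= 2 columns"
                    )
                query_id = cols[0].strip()
                surface = canonicalize(cols[1])
                gold = frozenset(
                    g.strip() for g in cols[2].split(";") if g.strip()
                ) if len(cols) > 2 else frozenset()
                language = "und"
                variants: list[str] = []
            else:
                record = json.loads(line)
                query_id = str(record["query_id"])
                surface = canonicalize(record["surface"])
                gold = frozenset(record.get("gold_concept_ids", []))
                language = record.get("language", "und")
                variants = [canonicalize(v) for v in record.get("translations", [])]
            if not surface:
                raise LexiconError(f"{path}: line {lineno}: empty surface")
            if query_id in seen_ids:
                raise LexiconError(
                    f"{path}: line {lineno}: duplicate query_id {query_id!r}"
                )
            seen_ids.add(query_id)
            translations = None
            if variants:
                deduped: list[str] = []
                for v in variants:
                    if v and v not in deduped:
                        deduped.append(v)
                translations = TranslationSet(
                    variants=[(v, frozenset({"file"})) for v in deduped]
                )
            queries.append(
                Query(
                    query_id=query_id,
                    surface=surface,
                    language=language,
                    gold_concept_ids=gold,
                    translations=translations,
                )
            )
    return queries


def write_queries(queries: list[Query], path) -> None:
    """Write queries as JSON-lines (inverse of ``read_queries(format='jsonl')``)."""
    with open(path, "w", encoding="utf-8") as handle:
        for q in queries:
            record = {
                "query_id": q.query_id,
                "surface": q.surface,
                "language": q.language,
                "gold_concept_ids": sorted(q.gold_concept_ids),
            }
            if q.translations is not None:
                record["translations"] = q.translations.texts()
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")
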