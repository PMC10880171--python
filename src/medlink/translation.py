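"""Multi-source translation as a provider contract with a deterministic mock.

Real deployments translate source-language terms through several web
engines and pool the results; variant spellings of the same concept
("lipid deposition disorder" vs. "liposis") all get a chance to match the
dictionary.  Here the engines are modeled as providers: any object with a
``name`` and a ``translate(text) -> list[str]`` method.  The shipped
implementation is a table-driven mock, so unification and downstream
scoring are fully deterministic and network-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from medlink.lexicon import canonicalize

logger = logging.getLogger(__name__)


class TranslationError(RuntimeError):
    """All providers failed for a query."""


class ProviderError(RuntimeError):
    """A single provider failed; carries the provider name."""

    def __init__(self, provider_name: str, message: str = "") -> None:
        self.provider_name = provider_name
        super().__init__(f"provider {provider_name!r} failed: {message}")


@runtime_checkable
class TranslationProvider(Protocol):
    """Contract for a translation backend."""

    name: str

    def translate(self, text: str) -> list[str]:
        """Candidate translations for ``text``; empty list if none."""
        ...


@dataclass(frozen=True)
class TranslationSet:
    """Unified variant set for one query.

    ``variants`` is an ordered list of (canonical text, contributing
    provider names); texts are unique, order is first-seen across providers
    in the configured provider sequence.
    """

    variants: tuple[tuple[str, frozenset[str]], ...] = ()

    def __init__(self, variants=()) -> None:
        object.__setattr__(
            self,
            "variants",
            tuple((text, frozenset(providers)) for text, providers in variants),
        )
        seen: set[str] = set()
        for text, providers in self.variants:
            if text in seen:
                raise ValueError(f"duplicate variant text {text!r}")
            if not providers:
                raise ValueError(f"variant {text!r} has an empty provider set")
            seen.add(text)

    def texts(self) -> list[str]:
        return [text for text, _ in self.variants]

    def __len__(self) -> int:
        return len(self.variants)


class MockTranslationProvider:
    """Deterministic table-driven provider.

    The table maps canonical source terms to ordered candidate translations;
    loadable from a TSV of ``source_term TAB translation`` (several rows per
    source allowed, file order preserved).
    """

    def __init__(self, name: str, table: dict[str, list[str]]) -> None:
        self.name = name
        self._table = {
            canonicalize(src): [canonicalize(t) for t in targets]
            for src, targets in table.items()
        }

    @classmethod
    def from_tsv(cls, name: str, path) -> "MockTranslationProvider":
        table: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                table.setdefault(cols[0], []).append(cols[1])
        return cls(name, table)

    def translate(self, text: str) -> list[str]:
        out = []
        for candidate in self._table.get(canonicalize(text), []):
            if candidate and candidate not in out:
                out.append(candidate)
        return out


def translate(provider: TranslationProvider, text: str) -> list[str]:
    """Canonicalized candidate translations from one provider.

    An empty list is a legal outcome (the provider has no output for the
    term).  Provider failures surface as :class:`ProviderError` carrying the
    provider name so callers can continue with the remaining providers.
    """
    if not text:
        raise ValueError("cannot translate empty text")
    try:
        raw = provider.translate(text)
    except ProviderError:
        raise
    except Exception as exc:  # provider backends may raise anything
        raise ProviderError(provider.name, str(exc)) from exc
    out: list[str] = []
    for candidate in raw:
        candidate = canonicalize(candidate)
        if candidate and candidate not in out:
            out.append(candidate)
    return out


def unify_translations(
    text: str, providers: list[TranslationProvider]
) -> TranslationSet:
    """Union of all providers' variants, tagged with contributing providers.

    Variant order is first-seen order across the fixed provider sequence,
    which makes downstream tie-breaking reproducible.  If some providers
    fail, the union is taken over the succeeding ones (warning logged); if
    all fail, :class:`TranslationError` is raised.
    """
    if not providers:
        raise ValueError("at least one provider is required")
    order: list[str] = []
    contributors: dict[str, set[str]] = {}
    n_failed = 0
    for provider in providers:
        try:
            candidates = translate(provider, text)
        except ProviderError as exc:
            logger.warning("skipping failed provider: %s", exc)
            n_failed += 1
            continue
        for candidate in candidates:
            if candidate not in contributors:
                order.append(candidate)
                contributors[candidate] = set()
            contributors[candidate].add(provider.name)
    if n_failed == len(providers):
        raise TranslationError(f"all {len(providers)} providers failed for {text!r}")
    return TranslationSet(
        variants=[(v, frozenset(contributors[v])) for v in order]
    )
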