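"""OvidSP-style retrieval semantics over an in-memory corpus.

Two field scopes are emulated, mirroring Ovid Medline's field suffixes:

``mp``
    multi-purpose: a term matches if its token sequence occurs contiguously
    (case-insensitive, at word boundaries) in the title, the abstract, or
    the word sequence of any MeSH descriptor attached to the record. This is
    why a textword like *cardiomyopathy* retrieves records indexed with
    *Cardiomyopathy, Dilated* even when the word is absent from the text.
``sh``
    subject heading: the term must equal a MeSH descriptor (case- and
    punctuation-insensitive, compared as token sequences). Subheadings and
    the major-topic flag are ignored; there is no tree explosion.

Strategies are ordered lists of terms combined with OR, rendered to and
parsed from Ovid's numbered-line syntax (``1  heart failure.mp.`` ...
``Or/1-N``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from ._text import contains_sequence, token_key
from .corpus import Corpus
from .records import BibRecord

__all__ = [
    "SearchTerm",
    "SearchStrategy",
    "match",
    "retrieve",
    "retrieve_ordered",
    "render_ovid",
    "parse_ovid",
    "OvidSyntaxError",
]

_SCOPES = ("mp", "sh")


@dataclass(frozen=True)
class SearchTerm:
    """A single searchable term: free text plus its field scope."""

    text: str
    scope: str = "mp"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("search term text must be non-empty")
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}, got {self.scope!r}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return token_key(self.text)

    def render(self) -> str:
        return f"{self.text.lower()}.{self.scope}."


@dataclass
class SearchStrategy:
    """An ordered OR-combination of unique search terms."""

    terms: list[SearchTerm] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(t.tokens, t.scope) for t in self.terms]
        if len(keys) != len(set(keys)):
            raise ValueError("strategy terms must be unique (text + scope)")
        if self.labels and len(self.labels) != len(self.terms):
            raise ValueError("labels, when given, must be one per term")
        if not self.labels:
            self.labels = [f"T{i + 1}" for i in range(len(self.terms))]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def with_term(self, term: SearchTerm, label: str | None = None) -> "SearchStrategy":
        return SearchStrategy(
            self.terms + [term], self.labels + [label or f"T{len(self.terms) + 1}"]
        )

    def term_set(self) -> frozenset[tuple[tuple[str, ...], str]]:
        return frozenset((t.tokens, t.scope) for t in self.terms)


@lru_cache(maxsize=4096)
def _record_token_fields(
    title: str, abstract: str, descriptors: tuple[str, ...]
) -> tuple[tuple[str, ...], ...]:
    return (token_key(title), token_key(abstract)) + tuple(
        token_key(d) for d in descriptors
    )


def match(term: SearchTerm, record: BibRecord) -> bool:
    """Does ``term`` retrieve ``record`` under its field scope?"""
    needle = term.tokens
    if term.scope == "sh":
        return any(token_key(h.descriptor) == needle for h in record.mesh)
    fields = _record_token_fields(
        record.title, record.abstract, tuple(h.descriptor for h in record.mesh)
    )
    return any(contains_sequence(f, needle) for f in fields)


def retrieve(
    strategy: SearchStrategy | SearchTerm | Iterable[SearchTerm], corpus: Corpus
) -> set[str]:
    """Record ids retrieved by the OR of the strategy's terms."""
    terms = _as_terms(strategy)
    hit: set[str] = set()
    for rec in corpus:
        if any(match(t, rec) for t in terms):
            hit.add(rec.record_id)
    return hit


def retrieve_ordered(
    strategy: SearchStrategy | SearchTerm | Iterable[SearchTerm], corpus: Corpus
) -> list[str]:
    """As :func:`retrieve` but preserving corpus order (for first-N screens)."""
    terms = _as_terms(strategy)
    return [r.record_id for r in corpus if any(match(t, r) for t in terms)]


def _as_terms(obj: SearchStrategy | SearchTerm | Iterable[SearchTerm]) -> list[SearchTerm]:
    if isinstance(obj, SearchTerm):
        return [obj]
    if isinstance(obj, SearchStrategy):
        return list(obj.terms)
    return list(obj)


# --- Ovid strategy text ------------------------------------------------------


class OvidSyntaxError(ValueError):
    """Raised when Ovid strategy text cannot be parsed; names the line."""


def render_ovid(strategy: SearchStrategy) -> str:
    """Render a strategy as numbered Ovid search lines.

    Multi-term strategies end with a combining line ``Or/1-N``. A single-term
    strategy renders without one — Ovid has no ``Or/1-1`` idiom.
    """
    if len(strategy) == 0:
        raise ValueError("cannot render an empty strategy")
    lines = [f"{i + 1}  {t.render()}" for i, t in enumerate(strategy.terms)]
    if len(strategy) > 1:
        lines.append(f"{len(strategy) + 1}  Or/1-{len(strategy)}")
    return "\n".join(lines) + "\n"


def parse_ovid(text: str | Iterable[str]) -> SearchStrategy:
    """Inverse of :func:`render_ovid`; tolerant of tab or space separators."""
    if isinstance(text, str):
        lines: Sequence[str] = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]
    terms: list[SearchTerm] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        # strip the leading line number (and optional '#' header column)
        parts = line.split(None, 1)
        if len(parts) == 2 and parts[0].rstrip(".").isdigit():
            line = parts[1].strip()
        if line.lower().startswith("or/"):
            continue
        if line.lower() in {"#", "searches", "# searches"}:
            continue
        matched = False
        for scope in _SCOPES:
            suffix = f".{scope}."
            if line.lower().endswith(suffix):
                terms.append(SearchTerm(line[: -len(suffix)].strip(), scope))
                matched = True
                break
        if not matched:
            raise OvidSyntaxError(
                f"line {lineno}: unknown field suffix in {line!r} "
                f"(expected .mp. or .sh.)"
            )
    if not terms:
        raise OvidSyntaxError("no search terms found in strategy text")
    return SearchStrategy(terms)
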