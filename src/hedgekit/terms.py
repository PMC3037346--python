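"""Candidate term identification by frequency analysis.

Over the term-identification subset of the gold standard, three analyses
propose candidate filter terms:

* MeSH descriptor frequency (scope ``sh``), after dropping descriptors on a
  semantic exclusion list (check tags for gender, age group, study design —
  frequent but not topical);
* single-textword frequency from titles and abstracts, stopwords omitted,
  ranked by total frequency the way a concordance lists them;
* candidate phrases, either mined as n-grams around the most frequent words
  or supplied as a curated list (phrase meaningfulness is a human judgment;
  the miner only proposes).

Every candidate carries its *record occurrence* — the number of distinct
records it retrieves — computed with the same matching semantics as the
query engine, so occurrence always equals ``|retrieve({term})|``. A cutoff
(by default 15% of the set size, rounded to the nearest count) shortlists
candidates for filter development.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Sequence

from ._text import pct, round_half_up, token_key, tokenize
from .corpus import Corpus
from .query import SearchTerm, match

__all__ = [
    "TermCandidate",
    "CutoffSpec",
    "mesh_frequency",
    "textword_frequency",
    "phrase_candidates",
    "apply_cutoff",
    "default_stopwords",
    "default_mesh_exclusions",
    "write_candidate_table",
]


@dataclass(frozen=True)
class TermCandidate:
    """A candidate filter term with its record occurrence in a given set."""

    text: str
    scope: str  # "mp" (title/abstract/subject-heading words) or "sh"
    record_occurrence: int
    occurrence_pct: float
    total_frequency: int | None = None  # token count, for concordance ranking

    def as_search_term(self) -> SearchTerm:
        return SearchTerm(self.text, self.scope)


@dataclass(frozen=True)
class CutoffSpec:
    """Occurrence cutoff as a fraction of set size.

    ``min_count(n)`` rounds to the nearest integer, so a 0.15 cutoff over an
    88-record set gives a threshold of 13 records.
    """

    fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"cutoff fraction must be in (0, 1], got {self.fraction}")

    def min_count(self, set_size: int) -> int:
        return int(round_half_up(self.fraction * set_size, 0))


def _load_wordlist(name: str) -> list[str]:
    text = resources.files("hedgekit.data").joinpath(name).read_text("utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def default_stopwords() -> frozenset[str]:
    """The bundled English stopword list (editable via config)."""
    return frozenset(w.lower() for w in _load_wordlist("stopwords.txt"))


def default_mesh_exclusions() -> list[str]:
    """Bundled check-tag exclusion list: gender, age group, study design."""
    return _load_wordlist("mesh_exclusions.txt")


def _rank(candidates: Iterable[TermCandidate], by_total: bool = False) -> list[TermCandidate]:
    key = (
        (lambda c: (-(c.total_frequency or 0), c.text.lower()))
        if by_total
        else (lambda c: (-c.record_occurrence, c.text.lower()))
    )
    return sorted(candidates, key=key)


def mesh_frequency(
    corpus: Corpus, exclusion_list: Sequence[str] = ()
) -> list[TermCandidate]:
    """Rank MeSH descriptors by the number of distinct records indexed with
    them (subheadings and major-topic flags ignored; one count per record).

    Descriptors on ``exclusion_list`` are dropped (case-insensitive). Ranked
    by record occurrence descending, ties alphabetical.
    """
    if len(corpus) == 0:
        raise ValueError("cannot analyse an empty corpus")
    excluded = {e.strip().lower() for e in exclusion_list}
    n = len(corpus)
    counts: Counter[str] = Counter()
    canonical: dict[str, str] = {}
    for rec in corpus:
        seen: set[str] = set()
        for h in rec.mesh:
            key = h.descriptor.lower()
            if key in excluded or key in seen:
                continue
            seen.add(key)
            canonical.setdefault(key, h.descriptor)
            counts[key] += 1
    return _rank(
        TermCandidate(canonical[k], "sh", c, pct(c, n)) for k, c in counts.items()
    )


def textword_frequency(
    corpus: Corpus, stopwords: frozenset[str] | Sequence[str] | None = None
) -> list[TermCandidate]:
    """Single textwords from titles and abstracts, stopwords removed.

    Ranked by total token frequency descending (the concordance ordering),
    alphabetical on ties; each candidate also carries its record occurrence
    under multi-purpose matching (title, abstract, or subject-heading words).
    """
    if len(corpus) == 0:
        raise ValueError("cannot analyse an empty corpus")
    stops = frozenset(w.lower() for w in (stopwords if stopwords is not None else default_stopwords()))
    n = len(corpus)
    totals: Counter[str] = Counter()
    for rec in corpus:
        for tok in tokenize(rec.title) + tokenize(rec.abstract):
            if tok not in stops and not tok.isdigit():
                totals[tok] += 1
    # record occurrence under mp semantics: subject-heading words count too
    occurrence: Counter[str] = Counter()
    for rec in corpus:
        mp_tokens = set(tokenize(rec.title)) | set(tokenize(rec.abstract))
        for h in rec.mesh:
            mp_tokens.update(token_key(h.descriptor))
        for tok in mp_tokens:
            if tok in totals:
                occurrence[tok] += 1
    return _rank(
        (
            TermCandidate(w, "mp", occurrence[w], pct(occurrence[w], n), totals[w])
            for w in totals
        ),
        by_total=True,
    )


def _phrase_occurrence(corpus: Corpus, phrase: str) -> int:
    term = SearchTerm(phrase, "mp")
    return sum(1 for rec in corpus if match(term, rec))


def phrase_candidates(
    corpus: Corpus,
    top_k_words: int = 110,
    max_len: int = 4,
    stopwords: frozenset[str] | Sequence[str] | None = None,
    curated: Sequence[str] | None = None,
) -> list[TermCandidate]:
    """Candidate multi-word phrases, ranked by record occurrence.

    With ``curated`` given, the listed phrases (and single words — a curated
    list may mix both) are scored directly; this is the override hook for a
    human-reviewed list. Otherwise contiguous n-grams (length 2..``max_len``)
    from titles/abstracts are proposed when they contain at least one of the
    ``top_k_words`` most frequent non-stop words and neither start nor end
    with a stopword or digit. The mined list is a reviewing aid, not a
    finished shortlist.
    """
    if curated is not None:
        n = len(corpus)
        return _rank(
            TermCandidate(p, "mp", occ, pct(occ, n))
            for p in curated
            for occ in (_phrase_occurrence(corpus, p),)
        )
    if len(corpus) == 0:
        raise ValueError("cannot analyse an empty corpus")
    if not 2 <= max_len <= 6:
        raise ValueError("max_len must be in 2..6")
    if top_k_words < 1:
        raise ValueError("top_k_words must be >= 1")
    stops = frozenset(
        w.lower() for w in (stopwords if stopwords is not None else default_stopwords())
    )
    top_words = {
        c.text for c in textword_frequency(corpus, stops)[:top_k_words]
    }
    phrase_records: dict[tuple[str, ...], set[str]] = {}
    for rec in corpus:
        for field_text in (rec.title, rec.abstract):
            toks = tokenize(field_text)
            for ln in range(2, max_len + 1):
                for i in range(len(toks) - ln + 1):
                    gram = tuple(toks[i : i + ln])
                    if gram[0] in stops or gram[-1] in stops:
                        continue  # stopword-boundary trimming
                    if gram[0].isdigit() or gram[-1].isdigit():
                        continue
                    if not any(t in top_words for t in gram):
                        continue
                    phrase_records.setdefault(gram, set()).add(rec.record_id)
    n = len(corpus)
    return _rank(
        TermCandidate(" ".join(g), "mp", len(ids), pct(len(ids), n))
        for g, ids in phrase_records.items()
    )


def apply_cutoff(
    candidates: Sequence[TermCandidate], cutoff: CutoffSpec, set_size: int
) -> list[TermCandidate]:
    """Keep candidates whose record occurrence meets the cutoff; order kept."""
    threshold = cutoff.min_count(set_size)
    return [c for c in candidates if c.record_occurrence >= threshold]


def write_candidate_table(candidates: Sequence[TermCandidate], sink: IO[str]) -> None:
    """Tab-delimited candidate table (term, scope, occurrence, percent)."""
    sink.write("term\tscope\trecord_occurrence\toccurrence_pct\n")
    for c in candidates:
        sink.write(f"{c.text}\t{c.scope}\t{c.record_occurrence}\t{c.occurrence_pct}\n")


def read_candidate_table(stream: IO[str] | Iterable[str]) -> list[TermCandidate]:
    """Inverse of :func:`write_candidate_table`."""
    out: list[TermCandidate] = []
    it = iter(stream)
    next(it, None)
    for line in it:
        if not line.strip():
            continue
        text, scope, occ, p = line.rstrip("\n").split("\t")
        out.append(TermCandidate(text, scope, int(occ), float(p)))
    return out
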