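"""Synthetic corpora with controlled term-occurrence structure.

Real filter-development corpora cannot be redistributed, so every pipeline
stage is exercised on generated data with the statistical features the
method cares about: a dominant anchor term present in most records,
partially overlapping satellite terms, and synonyms perfectly nested inside
the anchor (these produce the zero-marginal-gain eliminations that prune a
candidate list). Two entry points:

* :func:`generate` draws a corpus from a :class:`CorpusSpec` — per-term
  occurrence probabilities, conditional co-occurrence rules, noise text —
  reproducibly from a seed;
* :func:`table_fixtures` deterministically emits the named evaluation
  fixtures whose retrieval counts reproduce the published development and
  validation tables of the heart failure filter study design this toolkit
  implements; every fixture is self-verified on emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .builder import _compose_records, reconstruct_fixture
from .corpus import Corpus
from .query import SearchStrategy, SearchTerm, retrieve
from .records import BibRecord, MeshHeading
from ._text import token_key

__all__ = [
    "TermSpec",
    "CoOccurrenceRule",
    "CorpusSpec",
    "generate",
    "TableFixtures",
    "table_fixtures",
    "merge_demo_corpora",
    "abstract_demo_corpus",
]

_PLACEMENTS = ("title", "abstract", "mesh")


@dataclass(frozen=True)
class TermSpec:
    """A term to plant: text, which field it goes into, occurrence probability."""

    text: str
    placement: str = "title"
    prob: float = 0.5

    def __post_init__(self) -> None:
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"placement must be one of {_PLACEMENTS}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.prob}")


@dataclass(frozen=True)
class CoOccurrenceRule:
    """Plant ``dependent`` only in records that carry ``anchor``.

    With ``conditional_prob`` 1.0 the dependent term shadows the anchor
    exactly; any value gives perfect nesting (the dependent never occurs
    alone), which is what makes a term contribute zero marginal records.
    """

    dependent: str
    anchor: str
    conditional_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.conditional_prob <= 1.0:
            raise ValueError("conditional probability must be in [0, 1]")


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for one synthetic corpus."""

    n_records: int
    term_specs: tuple[TermSpec, ...] = ()
    co_rules: tuple[CoOccurrenceRule, ...] = ()
    noise_vocab_size: int = 40
    abstract_sentences: int = 2
    empty_abstract_prob: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if not 0.0 <= self.empty_abstract_prob <= 1.0:
            raise ValueError("empty_abstract_prob must be in [0, 1]")
        declared = {t.text for t in self.term_specs}
        for rule in self.co_rules:
            if rule.dependent not in declared or rule.anchor not in declared:
                raise ValueError(
                    f"co-occurrence rule {rule.dependent!r}|{rule.anchor!r} "
                    "references an undeclared term"
                )
            if rule.dependent == rule.anchor:
                raise ValueError("a term cannot depend on itself")


def generate(spec: CorpusSpec) -> Corpus:
    """Draw a corpus from ``spec``; same seed, same corpus, byte for byte."""
    from .builder import _load_noise_vocab  # shared collision-filtered vocabulary

    rng = np.random.default_rng(spec.seed)
    avoid = frozenset(
        tok for t in spec.term_specs for tok in token_key(t.text)
    )
    vocab = _load_noise_vocab(avoid)[: max(8, spec.noise_vocab_size)]
    dependents = {r.dependent for r in spec.co_rules}
    independent = [t for t in spec.term_specs if t.text not in dependents]
    by_text = {t.text: t for t in spec.term_specs}

    records: list[BibRecord] = []
    for i in range(spec.n_records):
        present: dict[str, TermSpec] = {}
        for t in independent:
            if rng.random() < t.prob:
                present[t.text] = t
        for rule in spec.co_rules:
            if rule.anchor in present and rng.random() < rule.conditional_prob:
                present[rule.dependent] = by_text[rule.dependent]
        title_terms = [t.text for t in present.values() if t.placement == "title"]
        abstract_terms = [
            t.text for t in present.values() if t.placement == "abstract"
        ]
        mesh = [
            MeshHeading(t.text.title())
            for t in present.values()
            if t.placement == "mesh"
        ]
        noise = lambda k: " ".join(rng.choice(vocab, size=k))  # noqa: E731
        title = " and ".join(title_terms + [noise(3)]).capitalize() + "."
        if rng.random() < spec.empty_abstract_prob:
            abstract = ""
        else:
            sentences = [
                noise(6).capitalize() + "." for _ in range(spec.abstract_sentences)
            ]
            sentences += [p.capitalize() + "." for p in abstract_terms]
            abstract = " ".join(sentences)
        records.append(
            BibRecord(
                record_id=f"SYN{i:05d}",
                title=title,
                abstract=abstract,
                mesh=mesh,
            )
        )
    return Corpus(spec.name, records)


# --- deterministic fixtures keyed to the published development tables --------

HEART_FAILURE_MP = SearchTerm("heart failure", "mp")
CARDIOMYOPATHY_MP = SearchTerm("cardiomyopathy", "mp")
VDL_SH = SearchTerm("ventricular dysfunction, left", "sh")
LVEF_MP = SearchTerm("left ventricular ejection fraction", "mp")
HEART_FAILURE_SH = SearchTerm("heart failure", "sh")
CHF_MP = SearchTerm("chf", "mp")
CONGESTIVE_MP = SearchTerm("congestive heart failure", "mp")
CHRONIC_MP = SearchTerm("chronic heart failure", "mp")
NYHA_MP = SearchTerm("new york heart association", "mp")

#: The four-term filter in its published line order.
FINAL_FILTER = SearchStrategy(
    [HEART_FAILURE_MP, VDL_SH, CARDIOMYOPATHY_MP, LVEF_MP]
)

#: Development-set union cardinalities (set size 394) driving the trace fixture.
DEVELOPMENT_UNIONS: dict[frozenset[SearchTerm], int] = {
    frozenset({HEART_FAILURE_MP}): 365,
    frozenset({HEART_FAILURE_MP, LVEF_MP}): 372,
    frozenset({HEART_FAILURE_MP, CARDIOMYOPATHY_MP}): 373,
    frozenset({HEART_FAILURE_MP, VDL_SH}): 373,
    frozenset({HEART_FAILURE_MP, CARDIOMYOPATHY_MP, LVEF_MP}): 378,
    frozenset({HEART_FAILURE_MP, CARDIOMYOPATHY_MP, VDL_SH}): 380,
    frozenset({HEART_FAILURE_MP, VDL_SH, LVEF_MP}): 376,
    frozenset({HEART_FAILURE_MP, CARDIOMYOPATHY_MP, VDL_SH, LVEF_MP}): 382,
}

#: Term-identification record occurrences (set size 88): the candidate table.
TERM_ID_COUNTS: dict[tuple[str, str], int] = {
    ("heart failure", "sh"): 62,
    ("ventricular dysfunction, left", "sh"): 14,
    ("heart failure", "mp"): 77,
    ("congestive heart failure", "mp"): 36,
    ("new york heart association", "mp"): 24,
    ("left ventricular ejection fraction", "mp"): 23,
    ("chf", "mp"): 20,
    ("chronic heart failure", "mp"): 17,
    ("cardiomyopathy", "mp"): 15,
}

#: Curated phrase/textword list for the term-identification analysis: the
#: shortlist a human reviewer would carry forward, plus two clinically
#: plausible phrases that fall below the occurrence cutoff in the fixture.
CURATED_PHRASES: tuple[str, ...] = (
    "heart failure",
    "congestive heart failure",
    "new york heart association",
    "left ventricular ejection fraction",
    "chf",
    "chronic heart failure",
    "cardiomyopathy",
    "diastolic dysfunction",
    "b-type natriuretic peptide",
)


@dataclass
class TableFixtures:
    """The named evaluation fixtures, each self-verified on emission."""

    term_id: Corpus
    development: Corpus
    dev_candidates: list[SearchTerm]
    validation: Corpus
    cochrane: Corpus
    screening: Corpus
    screening_labels: dict[str, bool]
    irrelevant: Corpus
    final_filter: SearchStrategy = field(default_factory=lambda: FINAL_FILTER)
    curated_phrases: tuple[str, ...] = CURATED_PHRASES


def _check(corpus: Corpus, term: SearchTerm, expected: int) -> None:
    got = len(retrieve(term, corpus))
    if got != expected:
        raise RuntimeError(
            f"fixture self-verification failed on {corpus.name!r}: "
            f"{term.render()} retrieves {got}, expected {expected}"
        )


def _term_id_fixture() -> Corpus:
    """88 records reproducing every candidate-table record occurrence.

    Built from index ranges: nested phrases (congestive/chronic heart
    failure) imply the bare ``heart failure`` bigram, the MeSH *Heart
    Failure* records sit inside the textword records, and every count not
    fixed by the candidate table overlaps maximally with the start of the
    anchor block.
    """
    n = 88
    plant: list[list[SearchTerm]] = [[] for _ in range(n)]

    def span(term: SearchTerm, start: int, count: int) -> None:
        for i in range(start, start + count):
            plant[i].append(term)

    span(CONGESTIVE_MP, 0, 36)          # embeds "heart failure"
    span(CHRONIC_MP, 36, 17)            # embeds "heart failure"
    span(HEART_FAILURE_MP, 53, 24)      # bare phrase; textword total 77
    span(HEART_FAILURE_SH, 0, 62)
    span(VDL_SH, 0, 14)
    span(NYHA_MP, 5, 24)
    span(LVEF_MP, 10, 23)
    span(CHF_MP, 0, 20)
    span(CARDIOMYOPATHY_MP, 20, 15)
    span(SearchTerm("diastolic dysfunction", "mp"), 40, 9)
    span(SearchTerm("b-type natriuretic peptide", "mp"), 60, 7)

    # check tags (excluded from frequency analysis) and sub-cutoff MeSH noise
    extra_mesh: dict[int, list[str]] = {}
    for i in range(n):
        tags = ["Humans"]
        if i < 44:
            tags.append("Male")
        if 30 <= i < 71:
            tags.append("Female")
        if 10 <= i < 51:
            tags.append("Middle Aged")
        if i < 12:
            tags.append("Hospitalization")
        if 50 <= i < 60:
            tags.append("Prognosis")
        extra_mesh[i] = tags

    avoid = frozenset(
        tok
        for text, _scope in TERM_ID_COUNTS
        for tok in token_key(text)
    ) | frozenset(token_key("diastolic dysfunction b-type natriuretic peptide"))
    corpus = Corpus(
        "term-identification",
        _compose_records(n, plant, avoid, "T", extra_mesh),
    )
    for (text, scope), expected in TERM_ID_COUNTS.items():
        _check(corpus, SearchTerm(text, scope), expected)
    return corpus


def _development_fixture() -> tuple[Corpus, list[SearchTerm]]:
    """394-record development set reproducing the permutation table.

    Satellite overlap *inside* the anchor and the nested synonym counts are
    not determined by the table; they are fixed deterministically at the
    candidate-table proportions scaled to 394 so the fixture is stable.
    """
    corpus, _ = reconstruct_fixture(
        n=394,
        unions=DEVELOPMENT_UNIONS,
        anchor_overlap={CARDIOMYOPATHY_MP: 67, VDL_SH: 63, LVEF_MP: 103},
        nested={
            CHF_MP: 89,
            CONGESTIVE_MP: 161,
            CHRONIC_MP: 76,
            NYHA_MP: 107,
            HEART_FAILURE_SH: 278,
        },
        name="filter-development",
        id_prefix="D",
    )
    candidates = [
        HEART_FAILURE_MP,
        CHF_MP,
        CONGESTIVE_MP,
        CHRONIC_MP,
        NYHA_MP,
        CARDIOMYOPATHY_MP,
        LVEF_MP,
        HEART_FAILURE_SH,
        VDL_SH,
    ]
    anchor_ids = retrieve(HEART_FAILURE_MP, corpus)
    for nested_term in (CHF_MP, CONGESTIVE_MP, CHRONIC_MP, NYHA_MP, HEART_FAILURE_SH):
        if not retrieve(nested_term, corpus) <= anchor_ids:
            raise RuntimeError(
                f"fixture self-verification failed: {nested_term.render()} "
                "escapes the anchor"
            )
    return corpus, candidates


def _held_out_fixture(
    name: str,
    id_prefix: str,
    n: int,
    hits: Mapping[SearchTerm, int],
    miss_mesh: Sequence[str],
) -> Corpus:
    """A validation-style corpus: per-term exclusive hit blocks, then misses
    carrying only the listed MeSH descriptors."""
    total_hits = sum(hits.values())
    if total_hits + len(miss_mesh) > n:
        raise ValueError("held-out fixture overfull")
    plant: list[list[SearchTerm]] = [[] for _ in range(n)]
    cursor = 0
    for term, count in hits.items():
        for i in range(cursor, cursor + count):
            plant[i].append(term)
        cursor += count
    extra_mesh = {
        total_hits + j: [descriptor] for j, descriptor in enumerate(miss_mesh)
    }
    avoid = frozenset(
        tok for t in FINAL_FILTER for tok in token_key(t.text)
    )
    corpus = Corpus(
        name, _compose_records(n, plant, avoid, id_prefix, extra_mesh)
    )
    got = len(retrieve(FINAL_FILTER, corpus))
    if got != total_hits:
        raise RuntimeError(
            f"fixture self-verification failed on {name!r}: filter retrieves "
            f"{got}, expected {total_hits}"
        )
    return corpus


def _validation_fixture() -> Corpus:
    return _held_out_fixture(
        "filter-validation",
        "V",
        394,
        {HEART_FAILURE_MP: 350, CARDIOMYOPATHY_MP: 20, VDL_SH: 10, LVEF_MP: 7},
        ["Pulmonary edema"] * 3
        + ["Coronary disease"]
        + ["Heart transplantation"]
        + ["Implantable defibrillators"] * 2,
    )


def _cochrane_fixture() -> Corpus:
    return _held_out_fixture(
        "cochrane-validation",
        "C",
        269,
        {HEART_FAILURE_MP: 240, CARDIOMYOPATHY_MP: 10, VDL_SH: 8, LVEF_MP: 5},
        ["Pulmonary edema", "Edema", "Edema", "Chronic diseases",
         "Cardiovascular diseases", "Heart diseases"],
    )


def _screening_fixture() -> tuple[Corpus, dict[str, bool], Corpus]:
    """A 210-record retrieval stream: 150 of the first 200 relevant, 50
    irrelevant with the per-term attribution planted, 10 unlabelled extras."""
    n = 210
    irrelevant_slots = [i for i in range(n) if i % 4 == 3][:50]
    irrelevant_plan: list[tuple[SearchTerm | None, MeshHeading | None]] = (
        [(HEART_FAILURE_MP, None)] * 17
        + [(None, MeshHeading("Heart Failure", ("drug therapy",)))] * 9
        + [(CARDIOMYOPATHY_MP, None)] * 11
        + [(None, MeshHeading("Ventricular Dysfunction, Left"))] * 11
        + [(LVEF_MP, None)] * 2
    )
    plant: list[list[SearchTerm]] = [[] for _ in range(n)]
    extra_mesh: dict[int, list[str]] = {}
    slot_of = {idx: k for k, idx in enumerate(irrelevant_slots)}
    labels: dict[str, bool] = {}
    for i in range(n):
        if i in slot_of:
            term, heading = irrelevant_plan[slot_of[i]]
            if term is not None:
                plant[i].append(term)
            if heading is not None:
                extra_mesh[i] = [heading.to_field().split("/")[0]]
                # subheading re-attached below via record construction
        else:
            plant[i].append(HEART_FAILURE_MP)
    avoid = frozenset(tok for t in FINAL_FILTER for tok in token_key(t.text))
    records = _compose_records(n, plant, avoid, "S", extra_mesh)
    # restore the subheading on the MeSH-only irrelevant records
    for i in slot_of:
        _term, heading = irrelevant_plan[slot_of[i]]
        if heading is not None and heading.subheadings:
            records[i].mesh = [heading]
    corpus = Corpus("precision-screening", records)
    for i in range(200):
        labels[records[i].record_id] = i not in slot_of
    irrelevant = Corpus(
        "irrelevant-retrievals", [records[i] for i in irrelevant_slots]
    )
    retrieved = retrieve(FINAL_FILTER, corpus)
    if len(retrieved) != n:
        raise RuntimeError(
            "fixture self-verification failed: screening stream must be "
            f"fully retrievable, got {len(retrieved)}/{n}"
        )
    if sum(labels.values()) != 150 or len(labels) != 200:
        raise RuntimeError("fixture self-verification failed: screening labels")
    return corpus, labels, irrelevant


def table_fixtures() -> TableFixtures:
    """Emit every published-table fixture, self-verified. Deterministic."""
    development, candidates = _development_fixture()
    screening, labels, irrelevant = _screening_fixture()
    return TableFixtures(
        term_id=_term_id_fixture(),
        development=development,
        dev_candidates=candidates,
        validation=_validation_fixture(),
        cochrane=_cochrane_fixture(),
        screening=screening,
        screening_labels=labels,
        irrelevant=irrelevant,
    )


# --- corpus-assembly demonstration fixtures ----------------------------------

def merge_demo_corpora() -> list[Corpus]:
    """Four tagged guideline sub-corpora: 1297 records with 216 planted
    cross-corpus duplicates, so the merged unique set has 1081 records."""
    sizes_new = [400, 270, 230, 181]  # fresh ids per corpus
    dups = [0, 80, 70, 66]  # ids repeated from earlier corpora
    names = ["guideline-A", "guideline-B", "guideline-C", "guideline-D"]
    all_ids: list[str] = []
    corpora: list[Corpus] = []
    next_id = 0
    for name, n_new, n_dup in zip(names, sizes_new, dups):
        ids = [all_ids[(7 * k) % len(all_ids)] for k in range(n_dup)] if n_dup else []
        # index stride 7 spreads duplicates across earlier corpora; dedupe
        ids = list(dict.fromkeys(ids))
        while len(ids) < n_dup:  # top up if the stride collided
            candidate = all_ids[len(ids) % len(all_ids)]
            if candidate not in ids:
                ids.append(candidate)
        fresh = [f"U{next_id + k:04d}" for k in range(n_new)]
        next_id += n_new
        all_ids.extend(fresh)
        records = [
            BibRecord(
                record_id=rid,
                title=f"Guideline citation {rid}.",
                abstract=f"Abstract for citation {rid}.",
                source_tags=[name],
            )
            for rid in ids + fresh
        ]
        corpora.append(Corpus(name, records))
    total = sum(len(c) for c in corpora)
    if total != 1297 or sum(len(c) for c in corpora) - 216 != 1081:
        raise RuntimeError("merge demo construction drifted from its design")
    return corpora


def abstract_demo_corpus() -> Corpus:
    """1044 records of which the last 168 lack an abstract."""
    records = [
        BibRecord(
            record_id=f"A{i:04d}",
            title=f"Citation number {i}.",
            abstract="" if i >= 876 else f"Abstract text for citation {i}.",
        )
        for i in range(1044)
    ]
    return Corpus("abstract-demo", records)
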