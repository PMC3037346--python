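"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import string

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from hedgekit.corpus import Corpus
from hedgekit.records import BibRecord, MeshHeading
from hedgekit.synthetic import table_fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_WORD = st.text(alphabet=string.ascii_lowercase, min_size=1, max_size=8)


@st.composite
def phrases(draw, max_words: int = 3) -> str:
    return " ".join(draw(st.lists(_WORD, min_size=1, max_size=max_words)))


@st.composite
def mesh_headings(draw) -> MeshHeading:
    return MeshHeading(
        descriptor=draw(phrases()).title(),
        subheadings=tuple(draw(st.lists(phrases(2), max_size=2))),
        major=draw(st.booleans()),
    )


@st.composite
def bib_records(draw, record_id: str | None = None) -> BibRecord:
    return BibRecord(
        record_id=record_id or draw(st.uuids()).hex[:10],
        title=draw(phrases(6)).capitalize() + ".",
        abstract=draw(st.one_of(st.just(""), phrases(12))),
        mesh=draw(st.lists(mesh_headings(), max_size=4)),
        pub_types=draw(st.lists(st.sampled_from(["Journal Article", "Review"]), max_size=2)),
        source_tags=draw(st.lists(st.sampled_from(["A", "B", "C"]), max_size=2, unique=True)),
        year=draw(st.one_of(st.none(), st.integers(1950, 2030))),
    )


@st.composite
def corpora(draw, min_size: int = 1, max_size: int = 12) -> Corpus:
    n = draw(st.integers(min_size, max_size))
    records = [draw(bib_records(record_id=f"H{i:04d}")) for i in range(n)]
    return Corpus("hypothesis", records)


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic published-table fixtures, built once per session."""
    return table_fixtures()


def make_record(rid: str, title: str, abstract: str = "", mesh=()) -> BibRecord:
    headings = [m if isinstance(m, MeshHeading) else MeshHeading(m) for m in mesh]
    return BibRecord(record_id=rid, title=title, abstract=abstract, mesh=headings)
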