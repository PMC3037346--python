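"""Gold-standard corpus assembly: merge, dedup, abstract filter, random split.

A gold standard here is a set of known-relevant records (e.g. the studies
cited by several clinical practice guidelines). Sub-corpora are merged with
first-occurrence-wins dedup by record id; the provenance tags of deleted
duplicates are transferred to the surviving record. Records without an
abstract can be set aside (term identification needs abstract text). The
final set is split at random into term-identification / filter-development /
filter-validation subsets, reproducibly from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .records import BibRecord

__all__ = ["Corpus", "SplitSpec", "merge_dedup", "require_abstract", "split",
           "write_split_manifest", "read_split_manifest"]


@dataclass
class Corpus:
    """A named, ordered collection of records with unique ids."""

    name: str
    records: list[BibRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"corpus {self.name!r}: duplicate record_id {dup!r}")
        self._index = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BibRecord]:
        return iter(self.records)

    def __contains__(self, record_id: object) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> BibRecord:
        return self._index[record_id]

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def subset(self, ids: Iterable[str], name: str) -> "Corpus":
        wanted = set(ids)
        return Corpus(name, [r for r in self.records if r.record_id in wanted])


@dataclass(frozen=True)
class SplitSpec:
    """Three split fractions (term-id, development, validation) plus the seed."""

    fractions: tuple[float, float, float] = (0.10, 0.45, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")


def merge_dedup(corpora: Sequence[Corpus], name: str = "merged") -> Corpus:
    """Merge corpora keeping the first occurrence of each record id.

    The survivor's ``source_tags`` become the union (in first-seen order) of
    the tags on every duplicate — the tag-transferral rule, so a record cited
    by several guidelines remembers all of them.
    """
    merged: dict[str, BibRecord] = {}
    for corpus in corpora:
        for rec in corpus:
            kept = merged.get(rec.record_id)
            if kept is None:
                # shallow copy so tag transfer never mutates the input corpus
                merged[rec.record_id] = BibRecord(
                    record_id=rec.record_id,
                    title=rec.title,
                    abstract=rec.abstract,
                    mesh=list(rec.mesh),
                    pub_types=list(rec.pub_types),
                    source_tags=list(rec.source_tags),
                    year=rec.year,
                )
            else:
                for tag in rec.source_tags:
                    if tag not in kept.source_tags:
                        kept.source_tags.append(tag)
    return Corpus(name, list(merged.values()))


def require_abstract(corpus: Corpus) -> tuple[Corpus, Corpus]:
    """Partition into (records with an abstract, records without)."""
    kept = [r for r in corpus if r.has_abstract]
    excluded = [r for r in corpus if not r.has_abstract]
    return (
        Corpus(f"{corpus.name}/with-abstract", kept),
        Corpus(f"{corpus.name}/no-abstract", excluded),
    )


def _nearest_int(x: float) -> int:
    return int(math.floor(x + 0.5))


def split(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus, Corpus]:
    """Random three-way partition into term-id / development / validation sets.

    Sizes are deterministic: the term-identification set gets the first
    fraction rounded to the nearest integer; the remainder is halved between
    development and validation per their fractions, with any odd record going
    to the development set. Membership is a uniform random partition drawn
    from a seeded permutation, so the same seed always reproduces the split.
    """
    n = len(corpus)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    f_term, f_dev, f_val = spec.fractions
    n_term = _nearest_int(f_term * n)
    remainder = n - n_term
    if f_dev + f_val > 0:
        n_dev = _nearest_int(remainder * f_dev / (f_dev + f_val))
        # odd-remainder convention: the extra record goes to development
        if f_dev == f_val and remainder % 2 == 1:
            n_dev = remainder // 2 + 1
    else:
        n_dev = 0
    n_val = remainder - n_dev
    if min(n_term, n_dev, n_val) <= 0:
        raise ValueError(
            f"split of {n} records with fractions {spec.fractions} "
            f"yields an empty set ({n_term}, {n_dev}, {n_val})"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    ids = corpus.ids
    term_ids = {ids[i] for i in order[:n_term]}
    dev_ids = {ids[i] for i in order[n_term : n_term + n_dev]}
    val_ids = {ids[i] for i in order[n_term + n_dev :]}
    return (
        corpus.subset(term_ids, "term-identification"),
        corpus.subset(dev_ids, "filter-development"),
        corpus.subset(val_ids, "filter-validation"),
    )


def write_split_manifest(
    sets: Sequence[Corpus], spec: SplitSpec, sink: IO[str]
) -> None:
    """Plain-text table (record_id, set name, seed) from which the split can
    be reconstructed, e.g. by pasting ids back into a database search."""
    sink.write("record_id\tset\tseed\n")
    for corpus in sets:
        for rec in corpus:
            sink.write(f"{rec.record_id}\t{corpus.name}\t{spec.seed}\n")


def read_split_manifest(stream: IO[str] | Iterable[str]) -> dict[str, list[str]]:
    """Inverse of :func:`write_split_manifest`: set name -> record ids."""
    out: dict[str, list[str]] = {}
    it = iter(stream)
    next(it, None)  # header
    for line in it:
        if not line.strip():
            continue
        rid, set_name, _seed = line.rstrip("\n").split("\t")
        out.setdefault(set_name, []).append(rid)
    return out
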