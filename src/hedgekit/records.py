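"""Bibliographic record model and MEDLINE / RIS flat-file I/O.

MEDLINE flat files are parsed through :mod:`Bio.Medline` after a light
normalization pass that validates tag lines and tolerates the single-space
``MH - `` separator dialect seen in some exports. MeSH headings are
normalized on ingest: a leading asterisk (the major-topic marker) is parsed
into the ``major`` flag, and subheadings after ``/`` are split out, so a
stored descriptor never embeds either. Substance-name fields (RN/NM) are
read but never treated as MeSH.

Guideline provenance travels in the ``SI`` (secondary source) tag so that a
record keeps the name of the corpus it came from across merge and round-trip.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import Medline

from ._text import normalize

logger = logging.getLogger(__name__)

__all__ = [
    "MeshHeading",
    "BibRecord",
    "MedlineParseError",
    "parse_medline",
    "write_medline",
    "parse_ris",
    "write_ris",
]


class MedlineParseError(ValueError):
    """Raised for a structurally malformed flat-file line; carries its number."""


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH descriptor as attached to a record.

    ``descriptor`` is the bare main heading: no leading ``*`` and no ``/``;
    the major-topic flag and any subheadings are held separately.
    """

    descriptor: str
    subheadings: tuple[str, ...] = ()
    major: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeSH descriptor must be non-empty")
        if self.descriptor.startswith("*") or "/" in self.descriptor:
            raise ValueError(
                f"descriptor must be normalized (no '*' or '/'): {self.descriptor!r}"
            )

    @classmethod
    def from_field(cls, raw: str) -> "MeshHeading":
        """Parse an MH field value such as ``*Heart Failure/drug therapy``.

        The asterisk may sit on the main heading or on a subheading; either
        way it is stripped and recorded as the major flag.
        """
        parts = [p.strip() for p in normalize(raw).split("/")]
        major = any(p.startswith("*") for p in parts)
        parts = [p.lstrip("*").strip() for p in parts]
        if not parts or not parts[0]:
            raise ValueError(f"empty MeSH heading field: {raw!r}")
        return cls(parts[0], tuple(s for s in parts[1:] if s), major)

    def to_field(self) -> str:
        text = self.descriptor
        if self.major:
            text = "*" + text
        if self.subheadings:
            text += "/" + "/".join(self.subheadings)
        return text


@dataclass
class BibRecord:
    """One bibliographic record (one MEDLINE citation)."""

    record_id: str
    title: str
    abstract: str = ""
    mesh: list[MeshHeading] = field(default_factory=list)
    pub_types: list[str] = field(default_factory=list)
    source_tags: list[str] = field(default_factory=list)
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.title:
            raise ValueError(f"record {self.record_id}: title must be non-empty")

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())

    def descriptors(self) -> list[str]:
        return [h.descriptor for h in self.mesh]


# --- MEDLINE -----------------------------------------------------------------

_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s{0,2}-\s?(.*)$")


def _normalize_medline_lines(lines: Iterable[str]) -> Iterator[str]:
    """Rewrite tag lines to the canonical ``TAG - value`` layout.

    Accepts both the standard two-space separator and the tighter ``MH - ``
    variant. A non-blank line that neither matches a tag nor is indented as
    a continuation is a structural error reported with its line number.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            yield ""
            continue
        if line[0].isspace():
            # continuation line: pad to the 6-column hang expected downstream
            yield "      " + line.strip()
            continue
        m = _TAG_RE.match(line)
        if m is None:
            raise MedlineParseError(
                f"line {lineno}: malformed MEDLINE tag line: {line!r}"
            )
        tag, value = m.group(1), m.group(2)
        yield f"{tag:<4}- {value}"


def _year_from_dp(dp: str | None) -> int | None:
    if not dp:
        return None
    m = re.search(r"\b(\d{4})\b", dp)
    return int(m.group(1)) if m else None


def parse_medline(stream: IO[str] | Iterable[str]) -> list[BibRecord]:
    """Parse MEDLINE flat-file text into records.

    Records without a PMID are rejected with a warning; parsing continues.
    Continuation lines are joined with single spaces.
    """
    text = "\n".join(_normalize_medline_lines(stream)) + "\n"
    records: list[BibRecord] = []
    for raw in Medline.parse(io.StringIO(text)):
        pmid = raw.get("PMID")
        if not pmid:
            logger.warning(
                "skipping MEDLINE record without PMID (title=%r)", raw.get("TI")
            )
            continue
        mesh = [MeshHeading.from_field(mh) for mh in raw.get("MH", [])]
        records.append(
            BibRecord(
                record_id=normalize(pmid),
                title=normalize(raw.get("TI", "") or ""),
                abstract=normalize(raw.get("AB", "") or ""),
                mesh=mesh,
                pub_types=[normalize(pt) for pt in raw.get("PT", [])],
                source_tags=[normalize(t) for t in raw.get("SI", [])],
                year=_year_from_dp(raw.get("DP")),
            )
        )
    return records


def write_medline(records: Iterable[BibRecord], sink: IO[str]) -> None:
    """Write records in MEDLINE flat-file layout; inverse of :func:`parse_medline`."""
    first = True
    for rec in records:
        if not first:
            sink.write("\n")
        first = False
        sink.write(f"PMID- {rec.record_id}\n")
        sink.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            sink.write(f"AB  - {rec.abstract}\n")
        if rec.year is not None:
            sink.write(f"DP  - {rec.year}\n")
        for pt in rec.pub_types:
            sink.write(f"PT  - {pt}\n")
        for h in rec.mesh:
            sink.write(f"MH  - {h.to_field()}\n")
        for tag in rec.source_tags:
            sink.write(f"SI  - {tag}\n")


# --- RIS ---------------------------------------------------------------------

_RIS_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")

# RIS keyword tags carry MeSH verbatim: no subheading structure is assumed.
_RIS_TITLE_TAGS = ("TI", "T1")
_RIS_ABSTRACT_TAGS = ("AB", "N2")


def parse_ris(stream: IO[str] | Iterable[str]) -> list[BibRecord]:
    """Parse RIS-formatted references into records.

    Keywords (``KW``) map to bare MeSH descriptors; ``C1`` carries provenance
    tags; unknown tags are ignored (logged at debug level).
    """
    records: list[BibRecord] = []
    current: dict[str, list[str]] = {}

    def flush() -> None:
        if not current:
            return
        rid = (current.get("ID") or current.get("AN") or [""])[0]
        title = next(
            (current[t][0] for t in _RIS_TITLE_TAGS if current.get(t)), ""
        )
        if not rid:
            logger.warning("skipping RIS record without ID/AN (title=%r)", title)
            current.clear()
            return
        abstract = next(
            (current[t][0] for t in _RIS_ABSTRACT_TAGS if current.get(t)), ""
        )
        year = None
        if current.get("PY"):
            m = re.search(r"\d{4}", current["PY"][0])
            year = int(m.group(0)) if m else None
        records.append(
            BibRecord(
                record_id=normalize(rid),
                title=normalize(title),
                abstract=normalize(abstract),
                mesh=[MeshHeading(normalize(kw)) for kw in current.get("KW", []) if kw],
                pub_types=[normalize(t) for t in current.get("M3", [])],
                source_tags=[normalize(t) for t in current.get("C1", [])],
                year=year,
            )
        )
        current.clear()

    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        m = _RIS_TAG_RE.match(line)
        if m is None:
            logger.debug("ignoring non-tag RIS line: %r", line)
            continue
        tag, value = m.group(1), m.group(2).strip()
        if tag == "ER":
            flush()
        elif tag in {"ID", "AN", "TI", "T1", "AB", "N2", "KW", "C1", "PY", "M3", "TY"}:
            current.setdefault(tag, []).append(value)
        else:
            logger.debug("ignoring unknown RIS tag %s", tag)
    flush()
    return records


def write_ris(records: Iterable[BibRecord], sink: IO[str]) -> None:
    """Write records in RIS layout; inverse of :func:`parse_ris`.

    MeSH headings are flattened to keywords (descriptor only), so the MEDLINE
    writer is the lossless one; RIS is for interchange with reference managers.
    """
    for rec in records:
        sink.write("TY  - JOUR\n")
        sink.write(f"ID  - {rec.record_id}\n")
        sink.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            sink.write(f"AB  - {rec.abstract}\n")
        if rec.year is not None:
            sink.write(f"PY  - {rec.year}\n")
        for h in rec.mesh:
            sink.write(f"KW  - {h.descriptor}\n")
        for tag in rec.source_tags:
            sink.write(f"C1  - {tag}\n")
        sink.write("ER  - \n")
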