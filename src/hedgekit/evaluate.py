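"""Recall validation, post-hoc precision screening, and error analyses.

Recall is measured against gold-standard sets of known-relevant records;
because such sets contain only relevant items, precision cannot be measured
inside them. It is instead estimated post hoc: the filter is run over an
unscreened corpus, the first N retrievals (in corpus order, standing in for
the database's default sort) are screened by a human, and precision is the
proportion judged relevant. Two error analyses complete the picture: the
MeSH indexing of missed relevant records, and the attribution of irrelevant
retrievals to the individual filter terms that brought them in.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from ._text import pct
from .corpus import Corpus
from .query import SearchStrategy, match, retrieve, retrieve_ordered

__all__ = [
    "EvaluationResult",
    "PrecisionScreen",
    "recall_eval",
    "precision_screen",
    "missed_report",
    "false_positive_attribution",
    "specificity_pct",
    "read_labels",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Recall of a strategy in a gold-standard set."""

    retrieved: int
    set_size: int
    recall_pct: float
    missed_ids: tuple[str, ...]


@dataclass(frozen=True)
class PrecisionScreen:
    """Post-hoc precision over the first N retrieved records."""

    screened_n: int
    relevant_n: int
    precision_pct: float
    labels: Mapping[str, bool]


def recall_eval(strategy: SearchStrategy, gold: Corpus) -> EvaluationResult:
    """Retrieved count, recall percentage (one decimal, half-up) and missed
    ids (in corpus order) of ``strategy`` in ``gold``."""
    if len(gold) == 0:
        raise ValueError("gold-standard corpus must be non-empty")
    hit = retrieve(strategy, gold)
    missed = tuple(rid for rid in gold.ids if rid not in hit)
    return EvaluationResult(len(hit), len(gold), pct(len(hit), len(gold)), missed)


def precision_screen(
    strategy: SearchStrategy,
    corpus: Corpus,
    first_n: int,
    labels: Mapping[str, bool],
) -> PrecisionScreen:
    """Precision over the first ``first_n`` records the strategy retrieves.

    ``labels`` maps record id to a human relevance judgment and must cover
    every screened record; missing labels raise with the offending ids.
    """
    if first_n <= 0:
        raise ValueError("first_n must be positive")
    screened = retrieve_ordered(strategy, corpus)[:first_n]
    unlabeled = [rid for rid in screened if rid not in labels]
    if unlabeled:
        raise ValueError(
            f"missing relevance labels for {len(unlabeled)} screened records: "
            + ", ".join(unlabeled[:10])
            + ("..." if len(unlabeled) > 10 else "")
        )
    relevant = sum(1 for rid in screened if labels[rid])
    return PrecisionScreen(
        screened_n=len(screened),
        relevant_n=relevant,
        precision_pct=pct(relevant, len(screened)),
        labels={rid: labels[rid] for rid in screened},
    )


def missed_report(result: EvaluationResult, gold: Corpus) -> pd.DataFrame:
    """MeSH descriptor frequency over the records the strategy missed.

    Columns ``descriptor`` and ``count``; sorted by count descending, then
    alphabetically. Shows what the missed records *were* indexed with, i.e.
    which concepts the filter has no handle on.
    """
    counts: Counter[str] = Counter()
    for rid in result.missed_ids:
        for descriptor in dict.fromkeys(gold[rid].descriptors()):
            counts[descriptor] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["descriptor", "count"])


def false_positive_attribution(
    strategy: SearchStrategy, irrelevant: Corpus
) -> pd.DataFrame:
    """Which filter terms are responsible for a set of irrelevant retrievals.

    Every record in ``irrelevant`` must be retrieved by the strategy. The
    returned table has one row per term: ``matched`` (records the term
    retrieves, alone or jointly) and ``unique_contribution`` (records no
    other term retrieves — what would be lost by dropping the term).
    """
    per_term: dict[str, set[str]] = {}
    for term in strategy:
        per_term[term.render()] = {
            r.record_id for r in irrelevant if match(term, r)
        }
    covered = set().union(*per_term.values()) if per_term else set()
    stray = [rid for rid in irrelevant.ids if rid not in covered]
    if stray:
        raise ValueError(
            "records not retrieved by the strategy cannot be attributed: "
            + ", ".join(stray[:10])
        )
    rows = []
    for name, ids in per_term.items():
        others = set().union(
            *(v for k, v in per_term.items() if k != name)
        ) if len(per_term) > 1 else set()
        rows.append((name, len(ids), len(ids - others)))
    return pd.DataFrame(
        rows, columns=["term", "matched", "unique_contribution"]
    ).sort_values(
        ["matched", "term"], ascending=[False, True], ignore_index=True
    )


def specificity_pct(correct_exclusions: int, irrelevant_total: int) -> float:
    """Specificity: irrelevant records correctly excluded, as a percentage.

    Only computable when an irrelevant-labelled corpus exists; a gold
    standard of relevant-only records cannot yield it.
    """
    return pct(correct_exclusions, irrelevant_total)


def read_labels(stream: IO[str] | Iterable[str]) -> dict[str, bool]:
    """Read a two-column (record_id, yes/no) relevance label file."""
    truthy = {"yes", "y", "true", "1", "relevant"}
    falsy = {"no", "n", "false", "0", "irrelevant"}
    labels: dict[str, bool] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("record_id"):
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) < 2:
            raise ValueError(f"label line {lineno}: expected two columns: {line!r}")
        rid, value = parts[0].strip(), parts[1].strip().lower()
        if value in truthy:
            labels[rid] = True
        elif value in falsy:
            labels[rid] = False
        else:
            raise ValueError(f"label line {lineno}: unrecognized judgment {value!r}")
    return labels
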