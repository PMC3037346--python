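"""Greedy recall-maximizing construction of an OR filter, with trace.

The development procedure: every shortlisted candidate is first searched
singly in the development set; the top performer becomes the filter's first
term (T1). Each remaining candidate is then trialled OR-ed onto the current
baseline, candidates contributing no additional records are eliminated
outright (under pure OR they can never recover), and the best unique
contributor is appended. This repeats until no candidate adds records. Every
trial evaluation is recorded, so the emitted trace reads like a published
search-permutation table; when two candidates tie for best gain, both
branches are explored and logged before the tie policy picks one.

``reconstruct_fixture`` inverts a printed permutation table: given the union
cardinalities of an anchor term with subsets of satellite terms, it plants
term memberships in a synthetic corpus so that every listed strategy
retrieves exactly its listed count (rejecting infeasible tables), which lets
a development trace be replayed without the original database.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Mapping, Sequence

from ._text import pct, token_key
from .corpus import Corpus
from .query import SearchStrategy, SearchTerm, retrieve
from .records import BibRecord, MeshHeading
from .terms import TermCandidate

__all__ = [
    "TrialStep",
    "DevelopmentTrace",
    "greedy_build",
    "reconstruct_fixture",
    "InfeasibleTableError",
    "write_trace_table",
]

_TIE_POLICIES = ("alphabetical", "sh_first")


def _tie_key(policy: str):
    if policy == "alphabetical":
        return lambda t: (t.text.lower(), t.scope)
    if policy == "sh_first":
        return lambda t: (0 if t.scope == "sh" else 1, t.text.lower())
    raise ValueError(f"unknown tie policy {policy!r}; expected one of {_TIE_POLICIES}")


@dataclass(frozen=True)
class TrialStep:
    """One trial evaluation: a candidate OR-ed onto a baseline strategy."""

    branch: str  # "" on the selected path before any tie; "a", "ab", ... inside tie branches
    baseline: tuple[str, ...]  # rendered terms of the baseline strategy
    candidate: SearchTerm
    retrieved: int
    recall_pct: float
    accepted: bool  # True if this candidate was appended within its branch


@dataclass
class DevelopmentTrace:
    """Full development record: all trials, the result, the casualties."""

    steps: list[TrialStep] = field(default_factory=list)
    selected: SearchStrategy = field(default_factory=SearchStrategy)
    selected_counts: list[int] = field(default_factory=list)
    eliminated: list[tuple[SearchTerm, str]] = field(default_factory=list)
    set_size: int = 0


def _as_search_terms(
    candidates: Sequence[TermCandidate | SearchTerm],
) -> list[SearchTerm]:
    out = []
    for c in candidates:
        out.append(c if isinstance(c, SearchTerm) else c.as_search_term())
    return out


def greedy_build(
    candidates: Sequence[TermCandidate | SearchTerm],
    development: Corpus,
    tie_break: str = "alphabetical",
    explore_ties: bool = True,
) -> DevelopmentTrace:
    """Build a filter by greedy forward selection on retrieval count.

    Parameters
    ----------
    candidates
        Shortlisted candidate terms (order is irrelevant; selection is by
        performance with ties resolved by ``tie_break``).
    development
        The development set the counts are measured in.
    tie_break
        ``"alphabetical"`` (default) or ``"sh_first"`` (prefer a subject
        heading over a textword on a tied gain).
    explore_ties
        When True, every tied best candidate's branch is developed and its
        trials recorded before the policy selects one; branches of a pure OR
        filter converge whenever the tied terms all end up selected.
    """
    terms = _as_search_terms(candidates)
    if not terms:
        raise ValueError("candidate list must be non-empty")
    if len(development) == 0:
        raise ValueError("development corpus must be non-empty")
    if len({(t.tokens, t.scope) for t in terms}) != len(terms):
        raise ValueError("candidate terms must be unique (text + scope)")
    key = _tie_key(tie_break)
    n = len(development)
    match_sets: dict[SearchTerm, frozenset[str]] = {
        t: frozenset(retrieve(t, development)) for t in terms
    }
    trace = DevelopmentTrace(set_size=n)

    def explore(
        baseline: list[SearchTerm],
        covered: frozenset[str],
        remaining: list[SearchTerm],
        branch: str,
        eliminate_globally: bool,
    ) -> tuple[list[SearchTerm], list[int]]:
        counts: list[int] = []
        while True:
            base_names = tuple(t.render() for t in baseline)
            rows: dict[SearchTerm, int] = {}
            gains: list[tuple[SearchTerm, frozenset[str]]] = []
            survivors: list[SearchTerm] = []
            for t in remaining:
                union = covered | match_sets[t]
                rows[t] = len(trace.steps)
                trace.steps.append(
                    TrialStep(branch, base_names, t, len(union), pct(len(union), n), False)
                )
                if len(union) > len(covered):
                    gains.append((t, union))
                    survivors.append(t)
                elif eliminate_globally:
                    reason = (
                        "retrieves no records"
                        if not baseline
                        else f"no additional records over {' OR '.join(base_names)}"
                    )
                    trace.eliminated.append((t, reason))
            if not gains:
                return baseline, counts
            best = max(len(u) for _, u in gains)
            tied = sorted((t for t, u in gains if len(u) == best), key=key)
            if len(tied) > 1 and explore_ties and len(branch) < 4:
                results = []
                for letter, t in zip(string.ascii_lowercase, tied):
                    union = covered | match_sets[t]
                    sub_remaining = [s for s in survivors if s is not t]
                    sub_branch = branch + letter
                    trace.steps.append(
                        TrialStep(
                            sub_branch, base_names, t, len(union), pct(len(union), n), True
                        )
                    )
                    results.append(
                        explore(
                            baseline + [t],
                            frozenset(union),
                            sub_remaining,
                            sub_branch,
                            eliminate_globally and letter == "a",
                        )
                    )
                chosen_terms, chosen_counts = results[0]
                return chosen_terms, counts + [best] + chosen_counts
            chosen = tied[0]
            union = covered | match_sets[chosen]
            row = trace.steps[rows[chosen]]
            trace.steps[rows[chosen]] = TrialStep(
                row.branch, row.baseline, row.candidate, row.retrieved,
                row.recall_pct, True,
            )
            baseline = baseline + [chosen]
            covered = frozenset(union)
            remaining = [s for s in survivors if s is not chosen]
            counts.append(len(covered))

    selected_terms, counts = explore([], frozenset(), list(terms), "", True)
    trace.selected = SearchStrategy(list(selected_terms))
    trace.selected_counts = counts
    return trace


# --- fixture reconstruction from printed union cardinalities -----------------


class InfeasibleTableError(ValueError):
    """The stated union cardinalities admit no corpus; names the violation."""


def _load_noise_vocab(avoid_tokens: frozenset[str]) -> list[str]:
    text = resources.files("hedgekit.data").joinpath("noise_vocab.txt").read_text("utf-8")
    vocab = [
        w.strip()
        for w in text.splitlines()
        if w.strip() and not w.lstrip().startswith("#")
    ]
    vocab = [w for w in vocab if w.lower() not in avoid_tokens]
    if len(vocab) < 8:
        raise RuntimeError("noise vocabulary too small after collision filtering")
    return vocab


def _plant(
    fields: dict[str, list[str]], term: SearchTerm
) -> None:
    if term.scope == "sh":
        fields["mesh"].append(term.text.title())
    else:
        fields["title"].append(term.text)


def _compose_records(
    n: int,
    plantings: list[list[SearchTerm]],
    avoid_tokens: frozenset[str],
    id_prefix: str,
    extra_mesh: Mapping[int, Sequence[str]] | None = None,
) -> list[BibRecord]:
    """Build n records; record i carries the terms in ``plantings[i]``.

    Planted textwords are joined with ``and`` so no token sequence can span
    two planted phrases; noise words are collision-filtered against every
    planted term's tokens.
    """
    vocab = _load_noise_vocab(avoid_tokens)
    records: list[BibRecord] = []
    for i in range(n):
        fields: dict[str, list[str]] = {"title": [], "mesh": []}
        for term in plantings[i]:
            _plant(fields, term)
        noise = [vocab[(i * 3 + j) % len(vocab)] for j in range(3)]
        title_bits = fields["title"] + [" ".join(noise[:2])]
        title = (" and ".join(title_bits)).strip().capitalize() + "."
        abstract = f"A report concerning {noise[0]} and {noise[2]} follow-up."
        mesh = [MeshHeading(d) for d in fields["mesh"]]
        for d in (extra_mesh or {}).get(i, ()):
            mesh.append(MeshHeading(d))
        records.append(
            BibRecord(
                record_id=f"{id_prefix}{i:04d}",
                title=title,
                abstract=abstract,
                mesh=mesh,
            )
        )
    return records


def reconstruct_fixture(
    n: int,
    unions: Mapping[frozenset[SearchTerm] | tuple, int],
    anchor_overlap: Mapping[SearchTerm, int] | None = None,
    nested: Mapping[SearchTerm, int] | None = None,
    name: str = "reconstructed",
    id_prefix: str = "D",
) -> tuple[Corpus, list[SearchTerm]]:
    """Build a corpus reproducing a table of OR-strategy retrieval counts.

    ``unions`` maps term sets to retrieval counts and must contain a single
    *anchor* term present in every key, with its singleton count given (the
    first-selected term of a development table). Satellite memberships
    outside the anchor are solved exactly by inclusion–exclusion; a union
    the table does not determine defaults to maximal nesting (the smaller
    satellite sits inside the larger). Memberships *inside* the anchor are
    not constrained by such a table: ``anchor_overlap`` sizes them, and
    ``nested`` plants terms wholly inside the anchor block (zero marginal
    gain by construction). Every record gets a noise title/abstract so the
    corpus parses and screens like real bibliographic data.

    Raises
    ------
    InfeasibleTableError
        If any implied region would need a negative size, or the records
        exceed ``n``; the message names the offending constraint.
    """
    norm: dict[frozenset[SearchTerm], int] = {
        frozenset(k): v for k, v in unions.items()
    }
    all_terms = sorted(set().union(*norm.keys()), key=lambda t: (t.text, t.scope))
    in_every = set(all_terms)
    for k in norm:
        in_every &= k
    anchors = [t for t in in_every if frozenset([t]) in norm]
    if len(anchors) != 1:
        raise InfeasibleTableError(
            "table must contain exactly one anchor term present in every "
            f"union with its singleton count; found {len(anchors)}"
        )
    anchor = anchors[0]
    anchor_count = norm[frozenset([anchor])]
    satellites = [t for t in all_terms if t != anchor]

    # outside-anchor union sizes U(S) for every satellite subset S
    u: dict[frozenset[SearchTerm], int] = {frozenset(): 0}
    for size in range(1, len(satellites) + 1):
        for combo in itertools.combinations(satellites, size):
            s = frozenset(combo)
            stated = norm.get(s | {anchor})
            if stated is not None:
                u[s] = stated - anchor_count
            else:  # undetermined union: maximal nesting default
                u[s] = max(u[s - {t}] for t in s)
            lower = max(u[s - {t}] for t in s) if size > 1 else 0
            if u[s] < lower:
                raise InfeasibleTableError(
                    f"union over {sorted(t.text for t in s)} ({u[s] + anchor_count}) "
                    f"is smaller than one of its sub-unions"
                )

    def names(ts) -> list[str]:
        return sorted(t.text for t in ts)

    # intersections outside the anchor, then exact-region sizes (Moebius)
    inter: dict[frozenset[SearchTerm], int] = {}
    for size in range(1, len(satellites) + 1):
        for combo in itertools.combinations(satellites, size):
            s = frozenset(combo)
            total = 0
            for r in range(1, size + 1):
                for sub in itertools.combinations(combo, r):
                    total += (-1) ** (r + 1) * u[frozenset(sub)]
            inter[s] = total
    region: dict[frozenset[SearchTerm], int] = {}
    for size in range(len(satellites), 0, -1):
        for combo in itertools.combinations(satellites, size):
            s = frozenset(combo)
            x = inter[s] - sum(
                region[v] for v in region if s < v
            )
            if x < 0:
                raise InfeasibleTableError(
                    f"region exactly covering {names(s)} would need size {x}"
                )
            region[s] = x
    outside_total = sum(region.values())
    if outside_total != u.get(frozenset(satellites), outside_total):
        raise InfeasibleTableError("inclusion-exclusion inconsistency in table")
    if anchor_count + outside_total > n:
        raise InfeasibleTableError(
            f"table needs {anchor_count + outside_total} records but n = {n}"
        )

    # memberships: anchor block, then one index block per outside region
    plantings: list[list[SearchTerm]] = [[] for _ in range(n)]
    for i in range(anchor_count):
        plantings[i].append(anchor)
    for j, (term, count) in enumerate(sorted(
        (anchor_overlap or {}).items(), key=lambda kv: kv[0].text
    )):
        if count > anchor_count:
            raise InfeasibleTableError(
                f"anchor overlap for {term.text!r} exceeds the anchor count"
            )
        start = (j * 37) % max(1, anchor_count - count + 1)
        for i in range(start, start + count):
            plantings[i].append(term)
    for j, (term, count) in enumerate(sorted(
        (nested or {}).items(), key=lambda kv: kv[0].text
    )):
        if count > anchor_count:
            raise InfeasibleTableError(
                f"nested count for {term.text!r} exceeds the anchor count"
            )
        start = (j * 53) % max(1, anchor_count - count + 1)
        for i in range(start, start + count):
            plantings[i].append(term)
    cursor = anchor_count
    for s in sorted(region, key=lambda s: (len(s), names(s))):
        for _ in range(region[s]):
            for term in sorted(s, key=lambda t: t.text):
                plantings[cursor].append(term)
            cursor += 1

    avoid = frozenset(
        tok
        for t in set(all_terms) | set(nested or {}) | set(anchor_overlap or {})
        for tok in token_key(t.text)
    )
    corpus = Corpus(name, _compose_records(n, plantings, avoid, id_prefix))

    for key_set, stated in norm.items():  # self-verification against the table
        got = len(retrieve(sorted(key_set, key=lambda t: t.text), corpus))
        if got != stated:
            raise InfeasibleTableError(
                f"self-verification failed for {names(key_set)}: "
                f"planted {got}, table says {stated}"
            )
    terms_out = [anchor] + satellites + sorted(
        set(nested or {}), key=lambda t: t.text
    )
    return corpus, terms_out


def write_trace_table(trace: DevelopmentTrace, sink: IO[str]) -> None:
    """Tab-delimited development trace (baseline, candidate, count, recall)."""
    sink.write("branch\tbaseline\tcandidate\tretrieved\trecall_pct\taccepted\n")
    for s in trace.steps:
        base = " OR ".join(s.baseline) if s.baseline else "-"
        sink.write(
            f"{s.branch or '-'}\t{base}\t{s.candidate.render()}\t"
            f"{s.retrieved}\t{s.recall_pct}\t{'yes' if s.accepted else 'no'}\n"
        )
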