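"""Greedy forward selection and printed-table fixture reconstruction."""

import itertools

import pytest

from hedgekit.builder import (
    InfeasibleTableError,
    greedy_build,
    reconstruct_fixture,
)
from hedgekit.corpus import Corpus
from hedgekit.query import SearchTerm, retrieve
from hedgekit.synthetic import (
    CoOccurrenceRule,
    CorpusSpec,
    TermSpec,
    generate,
)

from conftest import make_record


def _exhaustive_best(candidates, covered, match_sets):
    """Independent per-step oracle: argmax retrieval count over candidates."""
    return max(len(covered | match_sets[t]) for t in candidates)


class TestGreedyBuild:
    def test_single_candidate_covering_everything(self):
        corpus = Corpus(
            "c", [make_record(str(i), "Heart failure report.", "a") for i in range(5)]
        )
        trace = greedy_build([SearchTerm("heart failure", "mp")], corpus)
        assert trace.selected_counts == [5]
        assert trace.steps[-1].recall_pct == 100.0

    def test_empty_candidates_is_an_error(self, fixtures):
        with pytest.raises(ValueError):
            greedy_build([], fixtures.development)

    def test_zero_gain_synonyms_eliminated_at_first_evaluation(self, fixtures):
        trace = greedy_build(fixtures.dev_candidates, fixtures.development)
        eliminated = {t.render() for t, _ in trace.eliminated}
        assert eliminated == {
            "chf.mp.",
            "congestive heart failure.mp.",
            "chronic heart failure.mp.",
            "new york heart association.mp.",
            "heart failure.sh.",
        }
        for _term, reason in trace.eliminated:
            assert "heart failure.mp." in reason

    def test_selected_counts_strictly_increase(self, fixtures):
        trace = greedy_build(fixtures.dev_candidates, fixtures.development)
        assert all(
            b > a for a, b in zip(trace.selected_counts, trace.selected_counts[1:])
        )

    def test_elimination_never_changes_the_final_retrieved_set(self):
        # run small random corpora with and without elimination-by-proxy:
        # the union of ALL positive-gain terms equals the selected filter's
        # reachable set, so dropping zero-gain terms is lossless.
        for seed in range(5):
            spec = CorpusSpec(
                n_records=25,
                term_specs=(
                    TermSpec("anchorword", "title", 0.7),
                    TermSpec("satellite", "title", 0.3),
                    TermSpec("shadow", "abstract", 0.5),
                ),
                co_rules=(CoOccurrenceRule("shadow", "anchorword", 0.5),),
                seed=seed,
            )
            corpus = generate(spec)
            terms = [SearchTerm(t.text, "mp") for t in spec.term_specs]
            trace = greedy_build(terms, corpus)
            everything = set()
            for t in terms:
                everything |= retrieve(t, corpus)
            assert retrieve(trace.selected, corpus) == everything

    def test_each_greedy_step_matches_exhaustive_argmax(self):
        for seed in range(12):
            spec = CorpusSpec(
                n_records=30,
                term_specs=tuple(
                    TermSpec(w, "title", p)
                    for w, p in [
                        ("alphaterm", 0.5),
                        ("betaterm", 0.4),
                        ("gammaterm", 0.3),
                        ("deltaterm", 0.25),
                        ("epsilonterm", 0.2),
                        ("zetaterm", 0.15),
                    ]
                ),
                seed=seed,
            )
            corpus = generate(spec)
            terms = [SearchTerm(t.text, "mp") for t in spec.term_specs]
            match_sets = {t: frozenset(retrieve(t, corpus)) for t in terms}
            trace = greedy_build(terms, corpus, explore_ties=False)
            covered: frozenset = frozenset()
            remaining = list(terms)
            for term, count in zip(trace.selected, trace.selected_counts):
                assert count == _exhaustive_best(remaining, covered, match_sets)
                covered = covered | match_sets[term]
                remaining = [t for t in remaining if t != term]

    def test_deterministic_given_inputs_and_policy(self, fixtures):
        a = greedy_build(fixtures.dev_candidates, fixtures.development)
        b = greedy_build(fixtures.dev_candidates, fixtures.development)
        assert a.steps == b.steps
        assert [t.render() for t in a.selected] == [t.render() for t in b.selected]

    def test_sh_first_policy_reproduces_published_term_order(self, fixtures):
        trace = greedy_build(
            fixtures.dev_candidates, fixtures.development, tie_break="sh_first"
        )
        assert [t.render() for t in trace.selected] == [
            "heart failure.mp.",
            "ventricular dysfunction, left.sh.",
            "cardiomyopathy.mp.",
            "left ventricular ejection fraction.mp.",
        ]

    def test_tie_branches_are_recorded_and_converge(self, fixtures):
        trace = greedy_build(fixtures.dev_candidates, fixtures.development)
        branches = {s.branch for s in trace.steps if s.branch}
        assert {"a", "b"} <= branches
        # both tie branches reach the same final count
        finals = {
            s.retrieved
            for s in trace.steps
            if s.accepted and len(s.baseline) == 3
        }
        assert finals == {382}


class TestReconstructFixture:
    A = SearchTerm("anchorphrase", "mp")
    B = SearchTerm("satellite", "mp")

    def test_forced_containment(self):
        corpus, _terms = reconstruct_fixture(
            4, {frozenset({self.A}): 3, frozenset({self.A, self.B}): 3}
        )
        assert retrieve(self.B, corpus) <= retrieve(self.A, corpus)
        assert len(retrieve(self.A, corpus)) == 3

    def test_infeasible_union_smaller_than_anchor(self):
        with pytest.raises(InfeasibleTableError):
            reconstruct_fixture(
                10, {frozenset({self.A}): 5, frozenset({self.A, self.B}): 4}
            )

    def test_overfull_table_rejected(self):
        with pytest.raises(InfeasibleTableError, match="records"):
            reconstruct_fixture(
                4, {frozenset({self.A}): 3, frozenset({self.A, self.B}): 6}
            )

    def test_every_listed_strategy_count_verifies(self, fixtures):
        from hedgekit.synthetic import DEVELOPMENT_UNIONS

        for key, expected in DEVELOPMENT_UNIONS.items():
            got = len(retrieve(sorted(key, key=lambda t: t.text), fixtures.development))
            assert got == expected, sorted(t.text for t in key)

    def test_three_satellite_regions_solved_exactly(self):
        C = SearchTerm("tertiary", "mp")
        unions = {
            frozenset({self.A}): 10,
            frozenset({self.A, self.B}): 14,
            frozenset({self.A, C}): 13,
            frozenset({self.A, self.B, C}): 15,
        }
        corpus, _ = reconstruct_fixture(30, unions)
        for key, expected in unions.items():
            assert len(retrieve(sorted(key, key=lambda t: t.text), corpus)) == expected
        # implied intersection outside the anchor: 4 + 3 - 5 = 2 records
        outside = retrieve([self.B, C], corpus) - retrieve(self.A, corpus)
        both = retrieve(self.B, corpus) & retrieve(C, corpus) - retrieve(self.A, corpus)
        assert len(both) == 2 and both <= outside
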