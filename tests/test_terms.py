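"""Frequency analysis: MeSH, textwords, phrases, record occurrence, cutoff."""

import re

import pytest

from hedgekit._text import pct, round_half_up
from hedgekit.corpus import Corpus
from hedgekit.query import SearchTerm, retrieve
from hedgekit.terms import (
    CutoffSpec,
    TermCandidate,
    apply_cutoff,
    default_mesh_exclusions,
    default_stopwords,
    mesh_frequency,
    phrase_candidates,
    textword_frequency,
)

from conftest import make_record


def test_half_up_percentage_rounding():
    assert pct(62, 88) == 70.5  # 70.4545...
    assert round_half_up(0.15 * 88, 0) == 13.0
    assert pct(1, 8) == 12.5


class TestMeshFrequency:
    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            mesh_frequency(Corpus("e", []), [])

    def test_no_mesh_gives_empty_list(self):
        c = Corpus("c", [make_record("1", "T.", "a")])
        assert mesh_frequency(c, []) == []

    def test_duplicate_descriptor_in_one_record_counted_once(self):
        from hedgekit.records import MeshHeading
        rec = make_record("1", "T.", "a")
        rec.mesh = [
            MeshHeading("Heart Failure", ("drug therapy",)),
            MeshHeading("Heart Failure", ("mortality",), major=True),
        ]
        (cand,) = mesh_frequency(Corpus("c", [rec]), [])
        assert cand.record_occurrence == 1

    def test_exclusion_list_is_case_insensitive(self):
        c = Corpus("c", [make_record("1", "T.", "a", mesh=["Humans", "Prognosis"])])
        cands = mesh_frequency(c, ["HUMANS"])
        assert [x.text for x in cands] == ["Prognosis"]

    def test_ranking_descending_then_alphabetical(self):
        records = [
            make_record("1", "T.", "a", mesh=["Beta", "Alpha"]),
            make_record("2", "U.", "a", mesh=["Beta", "Alpha", "Gamma"]),
        ]
        cands = mesh_frequency(Corpus("c", records), [])
        assert [x.text for x in cands] == ["Alpha", "Beta", "Gamma"]


class TestTextwordFrequency:
    def test_only_stopwords_gives_empty_list(self):
        c = Corpus("c", [make_record("1", "The of and.", "with for")])
        assert textword_frequency(c) == []

    def test_counts_match_brute_force_on_toy_corpus(self):
        texts = [
            ("Dyspnoea at rest.", "Severe dyspnoea reported."),
            ("Oedema assessment.", "Oedema and dyspnoea at follow up."),
            ("Renal outcomes.", ""),
            ("Rest and recovery.", "Renal function."),
            ("Dyspnoea scale.", ""),
        ]
        c = Corpus(
            "toy",
            [make_record(str(i), t, a) for i, (t, a) in enumerate(texts)],
        )
        cands = {x.text: x for x in textword_frequency(c, default_stopwords())}
        blob = " ".join(t + " " + a for t, a in texts).lower()
        for word in ("dyspnoea", "oedema", "renal", "rest"):
            assert cands[word].total_frequency == len(
                re.findall(rf"\b{word}\b", blob)
            )
            assert cands[word].record_occurrence == sum(
                1 for t, a in texts if word in (t + " " + a).lower()
            )

    def test_record_occurrence_includes_subject_heading_words(self):
        records = [
            make_record("1", "Cardiomyopathy in adults.", "a"),
            make_record("2", "Unrelated title.", "a", mesh=["Cardiomyopathy, Dilated"]),
        ]
        cands = {x.text: x for x in textword_frequency(Corpus("c", records))}
        assert cands["cardiomyopathy"].record_occurrence == 2
        assert cands["cardiomyopathy"].total_frequency == 1  # text only


class TestPhraseCandidates:
    def test_single_word_titles_yield_no_phrases(self):
        c = Corpus("c", [make_record("1", "Dyspnoea.", ""), make_record("2", "Oedema.", "")])
        assert phrase_candidates(c, top_k_words=5, max_len=3) == []

    def test_mined_phrase_occurrence_matches_substring_scan(self):
        c = Corpus(
            "c",
            [
                make_record("1", "Left ventricular ejection fraction measured.", ""),
                make_record("2", "Stable left ventricular ejection fraction.", ""),
                make_record("3", "No relevant content at all.", ""),
            ],
        )
        mined = {x.text: x for x in phrase_candidates(c, top_k_words=10, max_len=4)}
        gram = "left ventricular ejection fraction"
        assert mined[gram].record_occurrence == 2

    def test_phrases_never_start_or_end_with_stopword(self):
        c = Corpus(
            "c",
            [make_record("1", "Management of heart failure in the elderly.", "")] * 1,
        )
        for cand in phrase_candidates(c, top_k_words=10, max_len=3):
            toks = cand.text.split()
            assert toks[0] not in default_stopwords()
            assert toks[-1] not in default_stopwords()

    def test_curated_list_scored_by_engine_scan(self, fixtures):
        cands = phrase_candidates(fixtures.term_id, curated=fixtures.curated_phrases)
        for cand in cands:
            brute = sum(
                1
                for rid in fixtures.term_id.ids
                if rid in retrieve(SearchTerm(cand.text, "mp"), fixtures.term_id)
            )
            assert cand.record_occurrence == brute


class TestCutoff:
    def test_threshold_rounds_to_nearest_count(self):
        assert CutoffSpec(0.15).min_count(88) == 13
        assert CutoffSpec(0.15).min_count(100) == 15

    def test_all_below_threshold_gives_empty(self):
        cands = [TermCandidate("x", "mp", 5, 5.0), TermCandidate("y", "mp", 12, 12.0)]
        assert apply_cutoff(cands, CutoffSpec(0.15), 88) == []

    def test_filter_matches_brute_force_and_preserves_order(self):
        cands = [
            TermCandidate(f"t{i}", "mp", occ, pct(occ, 88))
            for i, occ in enumerate([30, 13, 12, 14, 1, 88])
        ]
        survivors = apply_cutoff(cands, CutoffSpec(0.15), 88)
        assert survivors == [c for c in cands if c.record_occurrence >= 13]


class TestCrossModuleConsistency:
    def test_occurrence_equals_engine_retrieval_for_every_candidate(self, fixtures):
        corpus = fixtures.term_id
        for cand in mesh_frequency(corpus, default_mesh_exclusions()):
            assert cand.record_occurrence == len(
                retrieve(cand.as_search_term(), corpus)
            ), cand.text
        for cand in textword_frequency(corpus)[:40]:
            assert cand.record_occurrence == len(
                retrieve(cand.as_search_term(), corpus)
            ), cand.text

    def test_stored_pct_recomputes_from_counts(self, fixtures):
        corpus = fixtures.term_id
        for cand in mesh_frequency(corpus, []):
            assert cand.occurrence_pct == pct(cand.record_occurrence, len(corpus))
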