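"""Lexicon construction and longest-match annotation, checked against a
brute-force all-candidates oracle."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from methodminer.corpus import Document, Paragraph
from methodminer.lexicon_annotator import (
    AnnotationError,
    annotate_document,
    annotate_text,
    build_lexicon,
    ingest_external_annotations,
    write_annotations_tsv,
)
from methodminer.method_classification import expand_robotic_set
from methodminer.coverage_analysis import profile_corpus

from _oracles import brute_force_annotate
from conftest import make_taxonomy


def lexicon_from(entries: dict[str, set[str]]):
    """Build a Lexicon via a throwaway taxonomy whose labels are the terms."""
    concepts: dict[str, set[str]] = {}
    for term, cids in entries.items():
        for cid in cids:
            concepts.setdefault(cid, set()).add(term)
    tax = make_taxonomy(
        {cid: set() for cid in concepts},
        labels={cid: sorted(terms)[0] for cid, terms in concepts.items()},
        synonyms={cid: set(sorted(terms)[1:]) for cid, terms in concepts.items()},
    )
    return build_lexicon(tax)


class TestBuildLexicon:
    def test_label_and_synonym_each_become_entries(self):
        tax = make_taxonomy(
            {"c1": set()},
            labels={"c1": "Blotting, Western"},
            synonyms={"c1": {"Western Blot"}},
        )
        lex = build_lexicon(tax)
        assert lex.entries == {
            "blotting, western": frozenset({"c1"}),
            "western blot": frozenset({"c1"}),
        }

    def test_shared_synonym_maps_to_all_owners(self):
        tax = make_taxonomy(
            {"c1": set(), "c2": set()},
            labels={"c1": "Assay One", "c2": "Assay Two"},
            synonyms={"c1": {"ELISA"}, "c2": {"ELISA"}},
        )
        lex = build_lexicon(tax)
        assert lex.entries["elisa"] == {"c1", "c2"}

    def test_entry_count_is_distinct_casefolded_strings(self):
        rng = random.Random(3)
        labels, synonyms, all_terms = {}, {}, []
        for i in range(20):
            cid = f"c{i}"
            labels[cid] = f"term {rng.randrange(12)}"
            synonyms[cid] = {f"TERM {rng.randrange(12)}", f"syn {i}"}
            all_terms += [labels[cid], *synonyms[cid]]
        tax = make_taxonomy({cid: set() for cid in labels}, labels=labels, synonyms=synonyms)
        assert len(build_lexicon(tax)) == len({t.lower() for t in all_terms})

    def test_method_subtree_restriction_drops_outside_concepts(self):
        tax = make_taxonomy(
            {"root": set(), "m": {"root"}, "out": set()},
            labels={"root": "methods", "m": "pcr", "out": "liver"},
            method_roots={"root"},
        )
        lex = build_lexicon(tax, restrict_to_method_subtree=True)
        assert set(lex.entries) == {"methods", "pcr"}


class TestAnnotateText:
    def test_empty_text_yields_no_mentions(self):
        lex = lexicon_from({"pcr": {"C1"}})
        assert annotate_text(lex, "") == []

    def test_case_insensitive_exact_matching_with_spans(self):
        lex = lexicon_from({"pcr": {"C1"}, "flow cytometry": {"C2"}})
        text = "We performed PCR and flow cytometry."
        found = {(m.concept_id, m.matched_text, m.start, m.end) for m in annotate_text(lex, text)}
        assert found == {
            ("C1", "PCR", 13, 16),
            ("C2", "flow cytometry", 21, 35),
        }

    def test_longest_match_wins_over_nested_term(self):
        lex = lexicon_from(
            {
                "real-time polymerase chain reaction": {"C1"},
                "polymerase chain reaction": {"C2"},
            }
        )
        text = "a real-time polymerase chain reaction assay"
        mentions = annotate_text(lex, text)
        assert [m.concept_id for m in mentions] == ["C1"]
        assert text[mentions[0].start : mentions[0].end] == "real-time polymerase chain reaction"

    def test_no_match_inside_alphanumeric_run(self):
        lex = lexicon_from({"pcr": {"C1"}})
        assert annotate_text(lex, "the ePCR2 device") == []
        assert [m.matched_text for m in annotate_text(lex, "(PCR)")] == ["PCR"]

    def test_ambiguous_entry_yields_one_mention_per_concept(self):
        lex = lexicon_from({"elisa": {"C1", "C2"}})
        mentions = annotate_text(lex, "an ELISA plate")
        assert [(m.concept_id, m.start, m.end) for m in mentions] == [
            ("C1", 3, 8),
            ("C2", 3, 8),
        ]

    def test_punctuation_inside_terms_must_match_exactly(self):
        lex = lexicon_from({"blotting, western": {"C1"}})
        assert annotate_text(lex, "western blotting was done") == []
        assert len(annotate_text(lex, "Blotting, Western was done")) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_equivalence_with_brute_force_oracle(self, seed):
        # adversarial small alphabet: terms overlap, nest and share prefixes
        rng = random.Random(seed)
        alphabet = "abc"
        terms = set()
        while len(terms) < rng.randrange(3, 10):
            n_words = rng.randrange(1, 4)
            terms.add(
                " ".join(
                    "".join(rng.choice(alphabet) for _ in range(rng.randrange(1, 4)))
                    for _ in range(n_words)
                )
            )
        entries = {t: {f"C{i % 4}"} for i, t in enumerate(sorted(terms))}
        lex = lexicon_from(entries)
        text = "".join(rng.choice("abc ,.-X") for _ in range(rng.randrange(0, 400)))
        got = [(m.concept_id, m.start, m.end) for m in annotate_text(lex, text)]
        assert sorted(got) == sorted(brute_force_annotate(entries, text))

    def test_determinism(self):
        lex = lexicon_from({"aa b": {"C1"}, "aa": {"C2"}, "b": {"C3"}})
        text = "aa b aa xb aa b"
        assert annotate_text(lex, text) == annotate_text(lex, text)

    def test_mentions_never_overlap(self):
        lex = lexicon_from({"ab": {"C1"}, "ba": {"C2"}, "aba": {"C3"}})
        mentions = annotate_text(lex, "ab aba ba ab")
        spans = sorted({(m.start, m.end) for m in mentions})
        assert all(s2 >= e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(text=st.text(alphabet="abAB xy.,-", max_size=300))
def test_matcher_invariants_on_arbitrary_text(text):
    """Spans are in-bounds and disjoint, matched_text is the verbatim
    slice, and matching is deterministic, whatever the input text."""
    lex = lexicon_from({"ab": {"C1"}, "ab ab": {"C2"}, "xy": {"C1", "C3"}, "b": {"C4"}})
    mentions = annotate_text(lex, text)
    assert mentions == annotate_text(lex, text)
    spans = sorted({(m.start, m.end) for m in mentions})
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    for m in mentions:
        assert 0 <= m.start < m.end <= len(text)
        assert text[m.start : m.end] == m.matched_text


class TestAnnotateDocument:
    def test_term_in_abstract_is_ignored(self):
        lex = lexicon_from({"pcr": {"C1"}})
        doc = Document("d1", [Paragraph("PCR everywhere", "abstract")])
        assert annotate_document(lex, doc) == []

    def test_paragraph_indices_point_into_full_document(self):
        lex = lexicon_from({"pcr": {"C1"}})
        doc = Document(
            "d1",
            [
                Paragraph("we ran PCR", "body"),
                Paragraph("methods", "heading"),
                Paragraph("more PCR here", "body"),
            ],
        )
        mentions = annotate_document(lex, doc)
        assert [(m.doc_id, m.paragraph_index) for m in mentions] == [("d1", 0), ("d1", 2)]
        for m in mentions:
            assert doc.paragraphs[m.paragraph_index].text[m.start : m.end] == m.matched_text

    def test_single_body_paragraph_equals_annotate_text(self):
        lex = lexicon_from({"pcr": {"C1"}, "flow cytometry": {"C2"}})
        text = "PCR then flow cytometry"
        doc = Document("d1", [Paragraph(text, "body")])
        via_doc = [(m.concept_id, m.start, m.end) for m in annotate_document(lex, doc)]
        via_text = [(m.concept_id, m.start, m.end) for m in annotate_text(lex, text)]
        assert via_doc == via_text


class TestExternalAnnotations:
    def test_header_only_tsv_gives_empty_result(self, tmp_path, chain_taxonomy):
        path = tmp_path / "ann.tsv"
        path.write_text("doc_id\tconcept_id\tstart\tend\tmatched_text\tparagraph_index\n")
        result = ingest_external_annotations(path, chain_taxonomy)
        assert result.mentions == [] and result.n_warnings == 0

    def test_round_trip_preserves_downstream_profiles(self, tmp_path):
        tax = make_taxonomy(
            {"root": set(), "m1": {"root"}, "m2": {"root"}},
            labels={"root": "methods", "m1": "pcr", "m2": "flow cytometry"},
            method_roots={"root"},
        )
        lex = build_lexicon(tax)
        docs = [
            Document("d1", [Paragraph("pcr and flow cytometry", "body")]),
            Document("d2", [Paragraph("just pcr", "body")]),
        ]
        mapping = expand_robotic_set(tax, {"m1"})
        internal = [m for d in docs for m in annotate_document(lex, d)]
        path = tmp_path / "ann.tsv"
        write_annotations_tsv(internal, path)
        external = ingest_external_annotations(path, tax)
        assert external.n_warnings == 0
        assert profile_corpus(docs, internal, mapping) == profile_corpus(
            docs, external.mentions, mapping
        )

    def test_unknown_concept_retained_and_counted(self, tmp_path, chain_taxonomy):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "doc_id\tconcept_id\tstart\tend\tmatched_text\tparagraph_index\n"
            "d1\tghost\t0\t3\txyz\t0\n"
        )
        result = ingest_external_annotations(path, chain_taxonomy)
        assert [m.concept_id for m in result.mentions] == ["ghost"]
        assert result.n_warnings == 1

    @pytest.mark.parametrize("row", ["d1\ta\t-1\t3\tx\t0\n", "d1\ta\t5\t2\tx\t0\n", "d1\ta\tq\t2\tx\t0\n"])
    def test_bad_spans_raise(self, tmp_path, chain_taxonomy, row):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "doc_id\tconcept_id\tstart\tend\tmatched_text\tparagraph_index\n" + row
        )
        with pytest.raises(AnnotationError):
            ingest_external_annotations(path, chain_taxonomy)
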