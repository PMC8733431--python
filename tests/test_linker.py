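import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litnet.corpus import EntityPage, LinkingCorpus, OntologyRecord, build_corpus
from litnet.linker import (
    Annotation,
    LinkerError,
    apply_acronym_overrides,
    detect_spots,
    extract_acronym_defs,
    filter_by_rho,
    score_all,
    score_rho,
)


class TestDetectSpots:
    def test_worked_example_spots(self, micro_corpus, worked_doc):
        anns = detect_spots(worked_doc.doc_id, worked_doc.text, micro_corpus)
        by_surface = {a.surface: a.uid for a in anns}
        assert by_surface == {
            "CD147": 1,
            "VEGF": 2,
            "placental growth factor": 3,
            "PLGF": 3,
        }

    def test_surface_equals_text_slice(self, micro_corpus, worked_doc):
        for a in detect_spots(worked_doc.doc_id, worked_doc.text, micro_corpus):
            assert worked_doc.text[a.start : a.end] == a.surface

    def test_no_corpus_term(self, micro_corpus):
        assert detect_spots("d", "nothing to see here", micro_corpus) == []

    def test_longest_first_leftmost(self):
        corpus = build_corpus(
            [OntologyRecord(source_id="g", name="growth factor")]
        )
        anns = detect_spots("d", "growth factor factor", corpus)
        assert len(anns) == 1
        assert (anns[0].start, anns[0].surface) == (0, "growth factor")

    def test_spans_never_overlap(self, micro_corpus):
        text = "placental growth factor and placental growth factor (PLGF)"
        anns = detect_spots("d", text, micro_corpus)
        spans = sorted((a.start, a.end) for a in anns)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_short_surfaces_case_sensitive(self, micro_corpus):
        assert detect_spots("d", "cd147 is lowercase", micro_corpus) == []
        assert detect_spots("d", "CD147 is uppercase", micro_corpus)

    def test_long_surfaces_case_insensitive(self, micro_corpus):
        anns = detect_spots("d", "Placental Growth Factor rises", micro_corpus)
        assert [a.uid for a in anns] == [3]


class TestScoreRho:
    def test_unambiguous_alone_is_one(self, micro_corpus):
        ann = Annotation("d", 0, 5, "CD147", 1)
        assert score_rho(ann, [ann], micro_corpus) == 1.0

    def test_two_way_ambiguity_forces_half(self):
        # one page titled X plus another page redirecting X -> two candidates
        corpus = LinkingCorpus()
        corpus.pages = {
            1: EntityPage(1, "X", "Genes", ""),
            2: EntityPage(2, "Other", "Diseases", ""),
        }
        corpus.redirects = {"X": 2}
        ann = Annotation("d", 0, 1, "X", 1)
        assert score_rho(ann, [ann], corpus) == 0.5

    def test_coherence_via_pagelink(self, micro_corpus):
        # BSG linked to VEGFA: relatedness 1, commonness 1 -> rho 1
        a = Annotation("d", 0, 5, "CD147", 1)
        b = Annotation("d", 10, 14, "VEGF", 2)
        assert score_rho(a, [a, b], micro_corpus) == 1.0

    def test_coherence_jaccard_hand_computed(self):
        # pagelinks: 1-3, 2-3 ; neighbours(1)={3}, neighbours(2)={3}
        # relatedness(1,2) = |{3}| / |{3}| = 1; commonness 1 -> rho 1
        # relatedness(1,4) = 0 (4 isolated): rho(1 vs {2,4}) = (1 + 0.5)/2
        corpus = LinkingCorpus()
        corpus.pages = {u: EntityPage(u, f"E{u}", "Genes", "") for u in (1, 2, 3, 4)}
        corpus.pagelinks = {(1, 3), (2, 3)}
        anns = [
            Annotation("d", 0, 2, "E1", 1),
            Annotation("d", 3, 5, "E2", 2),
            Annotation("d", 6, 8, "E4", 4),
        ]
        expected = (1.0 + (1.0 + 0.0) / 2) / 2  # (commonness + mean coherence)/2
        assert score_rho(anns[0], anns, corpus) == pytest.approx(expected)

    def test_requires_membership(self, micro_corpus):
        ann = Annotation("d", 0, 5, "CD147", 1)
        with pytest.raises(LinkerError):
            score_rho(ann, [], micro_corpus)

    def test_rho_always_in_unit_interval(self, worked_result):
        assert all(0.0 <= a.rho <= 1.0 for a in worked_result.annotations)


class TestFilterByRho:
    def test_strictly_above_threshold(self):
        anns = [
            Annotation("d", 0, 1, "a", 1, rho=0.9),
            Annotation("d", 2, 3, "b", 2, rho=0.1),
        ]
        assert filter_by_rho(anns, 0.3) == [anns[0]]

    def test_boundaries(self):
        anns = [Annotation("d", 0, 1, "a", 1, rho=0.0),
                Annotation("d", 2, 3, "b", 2, rho=1.0)]
        assert filter_by_rho(anns, 0.0) == [anns[1]]  # strict inequality
        assert filter_by_rho(anns, 1.0) == []

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(LinkerError):
            filter_by_rho([], bad)


class TestAcronyms:
    def test_parenthetical_definition(self, micro_corpus, worked_doc):
        anns = detect_spots(worked_doc.doc_id, worked_doc.text, micro_corpus)
        bindings = extract_acronym_defs(worked_doc.doc_id, worked_doc.text, anns)
        assert [(b.acronym, b.uid) for b in bindings] == [("PLGF", 3)]

    def test_orphan_parenthetical(self, micro_corpus):
        assert extract_acronym_defs("d", "(ACE2) appears alone", []) == []

    def test_initials_must_match_in_order(self):
        corpus = build_corpus(
            [OntologyRecord(source_id="v", name="vascular endothelial growth factor")]
        )
        text = "vascular endothelial growth factor (VEGF) signalling"
        anns = detect_spots("d", text, corpus)
        bindings = extract_acronym_defs("d", text, anns)
        assert len(bindings) == 1 and bindings[0].acronym == "VEGF"

    def test_mismatched_initials_rejected(self):
        corpus = build_corpus(
            [OntologyRecord(source_id="v", name="vascular endothelial growth factor")]
        )
        text = "vascular endothelial growth factor (XYZ) signalling"
        anns = detect_spots("d", text, corpus)
        assert extract_acronym_defs("d", text, anns) == []

    def test_override_rebinds_later_mentions(self):
        # TTF defined as a disease long form; a later TTF spot that the
        # gazetteer bound to a gene is re-pointed at the disease
        bindings_source = [
            Annotation("d", 0, 28, "thyroid transcription factor", 9, rho=0.8)
        ]
        from litnet.linker import AcronymBinding

        binding = AcronymBinding("d", "TTF", 9, defined_at=30)
        later = Annotation("d", 50, 53, "TTF", 4, rho=0.4)  # gene by gazetteer
        out = apply_acronym_overrides(bindings_source + [later], [binding])
        assert out[-1].uid == 9
        assert out[-1].rho == 0.8  # lifted to the long form's rho

    def test_mentions_before_definition_untouched(self):
        from litnet.linker import AcronymBinding

        early = Annotation("d", 0, 3, "TTF", 4, rho=0.4)
        binding = AcronymBinding("d", "TTF", 9, defined_at=10)
        assert apply_acronym_overrides([early], [binding]) == [early]

    def test_override_idempotent_and_span_preserving(self, worked_result):
        from litnet.linker import AcronymBinding

        anns = worked_result.annotations
        bindings = [AcronymBinding("worked-example", "PLGF", 3, defined_at=0)]
        once = apply_acronym_overrides(anns, bindings)
        twice = apply_acronym_overrides(once, bindings)
        assert once == twice
        assert [(a.start, a.end, a.surface) for a in once] == [
            (a.start, a.end, a.surface) for a in anns
        ]

    def test_no_bindings_identity(self):
        anns = [Annotation("d", 0, 3, "ABC", 1, rho=0.5)]
        assert apply_acronym_overrides(anns, []) == anns


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0, max_value=1))
def test_filter_monotone_in_threshold(threshold):
    anns = [
        Annotation("d", i, i + 1, "s", i, rho=r)
        for i, r in enumerate([0.0, 0.25, 0.5, 0.75, 1.0])
    ]
    kept = filter_by_rho(anns, threshold)
    assert all(a.rho > threshold for a in kept)
    assert [a for a in anns if a.rho > threshold] == kept
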