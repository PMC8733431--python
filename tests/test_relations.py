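import pytest

from litnet.fixtures import (
    WORKED_EXAMPLE_GOLD,
    triple_key,
)
from litnet.linker import Annotation
from litnet.relations import (
    ExtractionError,
    Triple,
    adjacent_sentence_triples,
    extract_triples,
    filter_bio_verbs,
    orient,
    prune_tokens,
)
from litnet.syntax import Sentence, Token
from litnet.weighting import VerbDictionary


def make_sentence(rows, doc_id="d", index=0, char_start=0, char_end=200):
    tokens = [Token(k, *row) for k, row in enumerate(rows)]
    return Sentence(doc_id, index, char_start, char_end, tokens)


class TestPrune:
    def test_determiners_and_preps_removed(self, worked_parse):
        (s,) = worked_parse
        kept = {t.text for t in prune_tokens(s)}
        assert "on" not in kept  # IN
        assert "and" not in kept  # CC
        assert {"CD147", "regulates", "VEGF", "isoforms"} <= kept

    def test_all_stopwords_prunes_to_nothing(self):
        rows = [
            ("the", "the", "DT", "det", 1),
            ("of", "of", "IN", "ROOT", 1),
        ]
        assert prune_tokens(make_sentence(rows)) == []

    def test_url_removed(self):
        rows = [
            ("http://x.y", "http://x.y", "ADD", "ROOT", 0),
            ("gene", "gene", "NN", "dep", 0),
        ]
        kept = prune_tokens(make_sentence(rows))
        assert [t.text for t in kept] == ["gene"]


class TestExtractTriples:
    def test_worked_example_two_triples(self, worked_result):
        got = {triple_key(t) for t in worked_result.triples}
        assert got == set(WORKED_EXAMPLE_GOLD)

    def test_single_annotation_no_triples(self, micro_corpus, worked_doc, worked_parse):
        (s,) = worked_parse
        only = [Annotation(worked_doc.doc_id, 0, 5, "CD147", 1, rho=1.0)]
        assert extract_triples(s, only, worked_doc.text) == []

    def test_inadmissible_path_blocks_pair(self):
        # B attaches through an adverbial clause: advcl is not admissible
        text = "A regulates while B rises."
        rows = [
            ("A", "a", "NNP", "nsubj", 1),
            ("regulates", "regulate", "VBZ", "ROOT", 1),
            ("while", "while", "IN", "mark", 4),
            ("B", "b", "NNP", "nsubj", 4),
            ("rises", "rise", "VBZ", "advcl", 1),
            (".", ".", "X", "punct", 1),
        ]
        s = make_sentence(rows, char_end=len(text))
        anns = [
            Annotation("d", 0, 1, "A", 1, rho=1.0),
            Annotation("d", 18, 19, "B", 2, rho=1.0),
        ]
        assert extract_triples(s, anns, text) == []

    def test_synonym_spots_merge_keeping_max_rho(self, micro_corpus, worked_doc, worked_parse):
        from dataclasses import replace

        from litnet.linker import detect_spots

        (s,) = worked_parse
        text = worked_doc.text
        spots = detect_spots("worked-example", text, micro_corpus)
        rho_for = {"CD147": 0.9, "placental growth factor": 0.6, "PLGF": 0.8}
        anns = [
            replace(a, rho=rho_for[a.surface])
            for a in spots
            if a.surface in rho_for
        ]
        triples = extract_triples(s, anns, text)
        assert len(triples) == 1  # long form and acronym collapse to one pair
        assert triples[0].target_rho == 0.8

    def test_no_self_loops(self, synthetic_bundle):
        spec, corpus, docs, analyzer = synthetic_bundle
        for d in docs:
            for s in d.sentences:
                anns = [
                    Annotation(d.document.doc_id, a, b, d.document.text[a:b], uid, rho=1.0)
                    for a, b, uid in d.gold_annotations
                    if s.char_start <= a and b <= s.char_end
                ]
                for t in extract_triples(s, anns, d.document.text):
                    assert t.source_uid != t.target_uid

    def test_triple_count_bounded_by_pairs(self, synthetic_bundle):
        spec, corpus, docs, analyzer = synthetic_bundle
        for d in docs:
            for s in d.sentences:
                anns = [
                    Annotation(d.document.doc_id, a, b, d.document.text[a:b], uid, rho=1.0)
                    for a, b, uid in d.gold_annotations
                    if s.char_start <= a and b <= s.char_end
                ]
                k = len({a.uid for a in anns})
                triples = extract_triples(s, anns, d.document.text)
                assert len(triples) <= k * (k - 1) // 2

    def test_unparsed_sentence_rejected(self):
        s = Sentence("d", 0, 0, 10, [])
        with pytest.raises(ExtractionError):
            extract_triples(s, [], "some text")


class TestOrient:
    def _triple(self, s, text, anns):
        (t,) = extract_triples(s, anns, text)
        return t

    def test_active_subject_is_source(self, worked_result, worked_parse):
        for t in worked_result.triples:
            assert t.directed and t.source_uid == 1

    def test_passive_swaps_roles(self):
        text = "VEGF is regulated by CD147."
        rows = [
            ("VEGF", "vegf", "NNP", "nsubjpass", 2),
            ("is", "be", "VBZ", "auxpass", 2),
            ("regulated", "regulate", "VBN", "ROOT", 2),
            ("by", "by", "IN", "agent", 2),
            ("CD147", "cd147", "NNP", "pobj", 3),
            (".", ".", "X", "punct", 2),
        ]
        s = make_sentence(rows, char_end=len(text))
        anns = [
            Annotation("d", 0, 4, "VEGF", 2, rho=1.0),
            Annotation("d", 21, 26, "CD147", 1, rho=1.0),
        ]
        t = orient(self._triple(s, text, anns), s)
        assert (t.source_uid, t.target_uid, t.directed) == (1, 2, True)

    def test_both_objects_undirected(self):
        text = "The study links BSG with VEGFA."
        rows = [
            ("The", "the", "DT", "det", 1),
            ("study", "study", "NN", "nsubj", 2),
            ("links", "link", "VBZ", "ROOT", 2),
            ("BSG", "bsg", "NNP", "dobj", 2),
            ("with", "with", "IN", "prep", 2),
            ("VEGFA", "vegfa", "NNP", "pobj", 4),
            (".", ".", "X", "punct", 2),
        ]
        s = make_sentence(rows, char_end=len(text))
        anns = [
            Annotation("d", 16, 19, "BSG", 1, rho=1.0),
            Annotation("d", 25, 30, "VEGFA", 2, rho=1.0),
        ]
        t = orient(self._triple(s, text, anns), s)
        assert not t.directed
        assert (t.source_uid, t.target_uid) == (1, 2)  # sentence order

    def test_idempotent(self, worked_result, worked_parse):
        (s,) = worked_parse
        for t in worked_result.triples:
            assert orient(t, s) == t

    def test_negation_flag_not_direction(self):
        text = "BSG does not regulate VEGFA."
        rows = [
            ("BSG", "bsg", "NNP", "nsubj", 3),
            ("does", "do", "VBZ", "aux", 3),
            ("not", "not", "RB", "neg", 3),
            ("regulate", "regulate", "VB", "ROOT", 3),
            ("VEGFA", "vegfa", "NNP", "dobj", 3),
            (".", ".", "X", "punct", 3),
        ]
        s = make_sentence(rows, char_end=len(text))
        anns = [
            Annotation("d", 0, 3, "BSG", 1, rho=1.0),
            Annotation("d", 22, 27, "VEGFA", 2, rho=1.0),
        ]
        t = orient(self._triple(s, text, anns), s)
        assert t.negated is True
        assert t.directed and (t.source_uid, t.target_uid) == (1, 2)


class TestAdjacentSentences:
    prev_text = "CD147 is overexpressed."
    cur_text = "It activates STAT3."

    def _sentences(self):
        prev_rows = [
            ("CD147", "cd147", "NNP", "nsubjpass", 2),
            ("is", "be", "VBZ", "auxpass", 2),
            ("overexpressed", "overexpress", "VBN", "ROOT", 2),
            (".", ".", "X", "punct", 2),
        ]
        cur_rows = [
            ("It", "it", "PRP", "nsubj", 1),
            ("activates", "activate", "VBZ", "ROOT", 1),
            ("STAT3", "stat3", "NNP", "dobj", 1),
            (".", ".", "X", "punct", 1),
        ]
        text = self.prev_text + " " + self.cur_text
        prev = make_sentence(prev_rows, index=0, char_start=0, char_end=23)
        cur = make_sentence(cur_rows, index=1, char_start=24, char_end=len(text))
        return prev, cur, text

    def test_pronoun_substitution(self):
        prev, cur, text = self._sentences()
        prev_anns = [Annotation("d", 0, 5, "CD147", 1, rho=1.0)]
        cur_anns = [Annotation("d", 37, 42, "STAT3", 5, rho=1.0)]
        (t,) = adjacent_sentence_triples(prev, cur, prev_anns, cur_anns, text)
        assert (t.source_uid, t.verb_lemma, t.target_uid, t.directed) == (
            1, "activate", 5, True,
        )

    def test_ambiguous_antecedent_blocks(self):
        prev, cur, text = self._sentences()
        prev_anns = [
            Annotation("d", 0, 5, "CD147", 1, rho=1.0),
            Annotation("d", 6, 8, "is", 7, rho=1.0),  # second entity
        ]
        cur_anns = [Annotation("d", 37, 42, "STAT3", 5, rho=1.0)]
        assert adjacent_sentence_triples(prev, cur, prev_anns, cur_anns, text) == []

    def test_nominal_subject_blocks(self):
        prev, cur, text = self._sentences()
        cur_nominal = make_sentence(
            [
                ("BSG", "bsg", "NNP", "nsubj", 1),
                ("activates", "activate", "VBZ", "ROOT", 1),
                ("STAT3", "stat3", "NNP", "dobj", 1),
                (".", ".", "X", "punct", 1),
            ],
            index=1,
            char_start=24,
            char_end=len(text),
        )
        prev_anns = [Annotation("d", 0, 5, "CD147", 1, rho=1.0)]
        assert (
            adjacent_sentence_triples(prev, cur_nominal, prev_anns, [], text) == []
        )

    def test_non_consecutive_rejected(self):
        prev, cur, text = self._sentences()
        cur.index = 5
        with pytest.raises(ExtractionError):
            adjacent_sentence_triples(prev, cur, [], [], text)


class TestBioFilter:
    def _t(self, verb):
        return Triple("d", 0, 1, 2, verb, directed=True)

    def test_dictionary_verb_kept(self):
        d = VerbDictionary.default()
        kept = filter_bio_verbs([self._t("regulate")], d, strict=True)
        assert len(kept) == 1

    def test_dissimilar_verb_dropped(self):
        d = VerbDictionary.default()
        assert filter_bio_verbs([self._t("resemble")], d, strict=True) == []

    def test_non_strict_identity(self):
        d = VerbDictionary.default()
        triples = [self._t("resemble"), self._t("regulate")]
        assert filter_bio_verbs(triples, d, strict=False) == triples


def test_triple_invariants():
    with pytest.raises(ExtractionError):
        Triple("d", 0, 1, 1, "regulate")
    with pytest.raises(ExtractionError):
        Triple("d", 0, 1, 2, "Regulate")
    with pytest.raises(ExtractionError):
        Triple("d", 0, 1, 2, "")
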