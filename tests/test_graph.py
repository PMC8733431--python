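import json

import networkx as nx
import pytest

from litnet.corpus import EntityPage, LinkingCorpus
from litnet.graph import (
    EvalResult,
    GraphEdge,
    GraphError,
    GraphNode,
    KnowledgeGraph,
    assemble,
    evaluate_against_gold,
    export_graph,
    import_graph_csv,
)
from litnet.relations import Triple
from litnet.weighting import CorpusStats, VerbDictionary


@pytest.fixture(scope="module")
def dictionary():
    return VerbDictionary.default()


def small_corpus(n=6):
    corpus = LinkingCorpus()
    corpus.pages = {u: EntityPage(u, f"E{u}", "Genes", "") for u in range(1, n + 1)}
    return corpus


class TestAssemble:
    def test_worked_example_graph_shape(self, worked_result):
        assert len(worked_result.graph.nodes) == 3
        assert len(worked_result.graph.edges) == 2
        assert all(e.directed for e in worked_result.graph.edges)
        assert {e.source_uid for e in worked_result.graph.edges} == {1}

    def test_empty_triples_empty_graph(self, dictionary):
        g = assemble([], CorpusStats.from_triples([]), small_corpus(), dictionary)
        assert g.nodes == {} and g.edges == []

    def test_repeated_triple_groups_with_support(self, dictionary):
        triples = [
            Triple("p", 0, 1, 2, "regulate", directed=True, source_rho=0.5, target_rho=0.5),
            Triple("p", 3, 1, 2, "regulate", directed=True, source_rho=1.0, target_rho=1.0),
        ]
        stats = CorpusStats.from_triples(triples)
        g = assemble(triples, stats, small_corpus(), dictionary)
        assert len(g.edges) == 1
        (e,) = g.edges
        assert e.support == 2
        assert e.provenance == [("p", 0), ("p", 3)]
        assert e.mrho == 0.5  # max rho pair across occurrences

    def test_directed_and_undirected_kept_distinct(self, dictionary):
        triples = [
            Triple("p", 0, 1, 2, "regulate", directed=True),
            Triple("p", 1, 2, 1, "regulate", directed=False),
        ]
        stats = CorpusStats.from_triples(triples)
        g = assemble(triples, stats, small_corpus(), dictionary)
        assert len(g.edges) == 2
        merged = assemble(triples, stats, small_corpus(), dictionary, merge_directions=True)
        assert len(merged.edges) == 1

    def test_permutation_invariant(self, dictionary):
        triples = [
            Triple("p", 0, 1, 2, "regulate", directed=True),
            Triple("q", 0, 3, 4, "activate", directed=True),
            Triple("p", 1, 1, 2, "regulate", directed=True),
        ]
        stats = CorpusStats.from_triples(triples)

        def snapshot(g):
            return sorted(
                (e.source_uid, e.target_uid, e.verb_lemma, e.directed, e.support,
                 round(e.tfidf, 12), round(e.mrho, 12))
                for e in g.edges
            )

        a = assemble(triples, stats, small_corpus(), dictionary)
        b = assemble(list(reversed(triples)), stats, small_corpus(), dictionary)
        assert snapshot(a) == snapshot(b)

    def test_unknown_uid_rejected(self, dictionary):
        t = Triple("p", 0, 1, 99, "regulate", directed=True)
        with pytest.raises(GraphError):
            assemble([t], CorpusStats.from_triples([t]), small_corpus(), dictionary)


def hand_graph(edges):
    g = KnowledgeGraph()
    for a, b in edges:
        for u in (a, b):
            g.nodes[u] = GraphNode(u, f"E{u}", "Genes")
        g.edges.append(
            GraphEdge(a, b, "regulate", directed=True, provenance=[("p", 0)])
        )
    return g


class TestEvaluate:
    def test_hand_counted_confusion(self):
        # graph holds 3 of 4 positives and 1 of 4 negatives
        positives = [(1, 2), (1, 3), (1, 4), (1, 5)]
        negatives = [(2, 3), (2, 4), (2, 5), (3, 4)]
        g = hand_graph([(1, 2), (1, 3), (1, 4), (2, 3)])
        r = evaluate_against_gold(g, positives, negatives)
        assert (r.tp, r.fn, r.fp, r.tn) == (3, 1, 1, 3)
        assert r.accuracy == pytest.approx(0.75)
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(0.75)
        assert r.ppv == pytest.approx(0.75)

    def test_perfect_graph(self):
        positives = [(1, 2), (3, 4)]
        negatives = [(1, 3), (2, 4)]
        g = hand_graph(positives)
        r = evaluate_against_gold(g, positives, negatives)
        assert r.accuracy == 1.0

    def test_empty_graph_forced_rates(self):
        positives = [(1, 2), (3, 4)]
        negatives = [(1, 3), (2, 4)]
        r = evaluate_against_gold(KnowledgeGraph(), positives, negatives)
        assert r.accuracy == 0.5
        assert r.sensitivity == 0.0
        assert r.specificity == 1.0

    def test_counts_partition_gold_lists(self):
        positives = [(1, 2), (1, 3), (2, 4)]
        negatives = [(3, 4), (2, 5)]
        g = hand_graph([(1, 2), (3, 4)])
        r = evaluate_against_gold(g, positives, negatives)
        assert r.tp + r.fn == len(positives)
        assert r.tn + r.fp == len(negatives)

    def test_direction_respected_on_request(self):
        g = hand_graph([(1, 2)])  # directed 1 -> 2
        assert evaluate_against_gold(g, [(2, 1)], [], ignore_direction=True).tp == 1
        assert evaluate_against_gold(g, [(2, 1)], [], ignore_direction=False).tp == 0

    def test_overlapping_gold_rejected(self):
        with pytest.raises(GraphError):
            evaluate_against_gold(KnowledgeGraph(), [(1, 2)], [(2, 1)])

    def test_undefined_rates_are_none(self):
        r = EvalResult(tp=0, fp=0, tn=0, fn=0)
        assert r.accuracy is None and r.ppv is None


class TestExport:
    def test_graphml_fig4_shape(self, worked_result, tmp_path):
        path = tmp_path / "g.graphml"
        export_graph(worked_result.graph, "graphml", path)
        from lxml import etree

        tree = etree.parse(str(path))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        assert len(tree.findall(".//g:node", ns)) == 3
        assert len(tree.findall(".//g:edge", ns)) == 2
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 3 and back.number_of_edges() == 2

    def test_cytoscape_json_structure(self, worked_result, tmp_path):
        path = tmp_path / "g.json"
        export_graph(worked_result.graph, "cytoscape-json", path)
        data = json.loads(path.read_text())
        assert set(data["elements"]) == {"nodes", "edges"}
        assert len(data["elements"]["nodes"]) == 3
        edge = data["elements"]["edges"][0]["data"]
        assert {"source", "target", "verb", "directed", "tfidf", "mrho",
                "bio", "support"} <= set(edge)

    def test_csv_round_trip_byte_identical(self, worked_result, tmp_path):
        first = tmp_path / "a"
        second = tmp_path / "b"
        export_graph(worked_result.graph, "csv", first)
        back = import_graph_csv(first)
        export_graph(back, "csv", second)
        for name in ("nodes.csv", "edges.csv"):
            assert (first / name).read_bytes() == (second / name).read_bytes()

    def test_empty_graph_valid_documents(self, tmp_path):
        g = KnowledgeGraph()
        export_graph(g, "graphml", tmp_path / "e.graphml")
        export_graph(g, "cytoscape-json", tmp_path / "e.json")
        export_graph(g, "csv", tmp_path / "csvdir")
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
        assert json.loads((tmp_path / "e.json").read_text())["elements"]["nodes"] == []
        assert import_graph_csv(tmp_path / "csvdir").edges == []

    def test_unknown_format_rejected(self, worked_result, tmp_path):
        with pytest.raises(GraphError):
            export_graph(worked_result.graph, "dot", tmp_path / "x")
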