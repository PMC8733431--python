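"""Knowledge-graph assembly, gold-standard evaluation and interchange I/O.

Triples are aggregated into a graph whose nodes are linked entities and
whose edges carry the verb lemma, a direction flag, the three weights
(tfidf, mrho, bio), a support count and per-sentence provenance.  A
directed and an undirected edge over the same entity pair and verb are
kept distinct by default.  Export formats: GraphML, Cytoscape-style
JSON, and a nodes.csv/edges.csv pair that round-trips losslessly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .corpus import LinkingCorpus
from .relations import Triple
from .weighting import (
    CorpusStats,
    EdgeKey,
    VerbDictionary,
    bio_score,
    corpus_tf_idf,
    edge_key,
)


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class GraphNode:
    uid: int
    title: str
    category: str


@dataclass
class GraphEdge:
    source_uid: int
    target_uid: int
    verb_lemma: str
    directed: bool
    tfidf: float = 0.0
    mrho: float = 0.0
    bio: float = 0.0
    negated: bool = False
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.provenance)

    @property
    def key(self) -> EdgeKey:
        return edge_key(self.source_uid, self.target_uid, self.verb_lemma, self.directed)


@dataclass
class KnowledgeGraph:
    nodes: dict[int, GraphNode] = field(default_factory=dict)
    edges: list[GraphEdge] = field(default_factory=list)

    def connects(self, a: int, b: int, respect_direction: bool = False) -> bool:
        for e in self.edges:
            if not respect_direction or not e.directed:
                if {e.source_uid, e.target_uid} == {a, b}:
                    return True
            elif (e.source_uid, e.target_uid) == (a, b):
                return True
        return False


def assemble(
    triples: Sequence[Triple],
    stats: CorpusStats,
    corpus: LinkingCorpus,
    dictionary: VerbDictionary | None = None,
    merge_directions: bool = False,
) -> KnowledgeGraph:
    """Group triples into weighted edges; nodes come from the corpus.

    mrho uses the maximum endpoint-confidence product seen across the
    edge's occurrences; tfidf is the corpus-level (summed) weight.
    """
    dictionary = dictionary or VerbDictionary.default()
    graph = KnowledgeGraph()
    groups: dict[tuple[EdgeKey, bool], list[Triple]] = {}
    for t in sorted(
        triples,
        key=lambda t: (t.doc_id, t.sentence_index, t.source_uid, t.target_uid, t.verb_lemma),
    ):
        for uid in (t.source_uid, t.target_uid):
            if uid not in corpus.pages:
                raise GraphError(f"triple {t} references unknown entity {uid}")
        directed = t.directed and not merge_directions
        groups.setdefault((edge_key(t.source_uid, t.target_uid, t.verb_lemma, directed), directed), []).append(t)
    for (key, directed), members in groups.items():
        rep = members[0]
        src, tgt = (rep.source_uid, rep.target_uid) if directed else (key.source_uid, key.target_uid)
        best_product = max(m.source_rho * m.target_rho for m in members)
        graph.edges.append(
            GraphEdge(
                source_uid=src,
                target_uid=tgt,
                verb_lemma=key.verb_lemma,
                directed=directed,
                tfidf=corpus_tf_idf(key, stats),
                mrho=best_product / 2,
                bio=bio_score(key.verb_lemma, dictionary),
                negated=any(m.negated for m in members),
                provenance=[(m.doc_id, m.sentence_index) for m in members],
            )
        )
    for e in graph.edges:
        for uid in (e.source_uid, e.target_uid):
            page = corpus.pages[uid]
            graph.nodes[uid] = GraphNode(uid, page.title, page.category)
    return graph


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the four derived rates (None when undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float | None:
        return _safe_div(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float | None:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _safe_div(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _safe_div(self.tp, self.tp + self.fp)


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate_against_gold(
    graph: KnowledgeGraph,
    positives: Sequence[tuple[int, int]],
    negatives: Sequence[tuple[int, int]],
    ignore_direction: bool = True,
) -> EvalResult:
    """Score the graph against known interacting / non-interacting pairs."""
    pos = {tuple(p) for p in positives}
    neg = {tuple(p) for p in negatives}
    overlap = {frozenset(p) for p in pos} & {frozenset(p) for p in neg}
    if overlap:
        raise GraphError(f"gold lists overlap: {sorted(map(sorted, overlap))}")
    tp = fp = tn = fn = 0
    for a, b in sorted(pos):
        if graph.connects(a, b, respect_direction=not ignore_direction):
            tp += 1
        else:
            fn += 1
    for a, b in sorted(neg):
        if graph.connects(a, b, respect_direction=not ignore_direction):
            fp += 1
        else:
            tn += 1
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


def read_gold_pairs(path: str | Path, corpus: LinkingCorpus) -> list[tuple[int, int]]:
    """Read a SOURCE,TARGET gold edge list; names resolve via titles."""
    titles = {p.title: p.uid for p in corpus.pages.values()}
    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            if len(row) < 2:
                continue
            a = titles.get(row[0], None)
            b = titles.get(row[1], None)
            if a is None or b is None:
                raise GraphError(f"gold pair {row[:2]} not in corpus")
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# export / import


def _to_networkx(graph: KnowledgeGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for node in graph.nodes.values():
        g.add_node(node.uid, title=node.title, category=node.category)
    for e in graph.edges:
        g.add_edge(
            e.source_uid,
            e.target_uid,
            verb=e.verb_lemma,
            directed=e.directed,
            tfidf=e.tfidf,
            mrho=e.mrho,
            bio=e.bio,
            negated=e.negated,
            support=e.support,
        )
    return g


def export_graph(graph: KnowledgeGraph, fmt: str, path: str | Path) -> None:
    """Write the graph as graphml, cytoscape-json, or a CSV pair.

    For ``csv`` the path is a directory receiving nodes.csv and
    edges.csv; the other formats write a single file.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_networkx(graph), path)
    elif fmt == "cytoscape-json":
        data = {
            "elements": {
                "nodes": [
                    {
                        "data": {
                            "id": str(n.uid),
                            "title": n.title,
                            "category": n.category,
                        }
                    }
                    for n in graph.nodes.values()
                ],
                "edges": [
                    {
                        "data": {
                            "source": str(e.source_uid),
                            "target": str(e.target_uid),
                            "verb": e.verb_lemma,
                            "directed": e.directed,
                            "tfidf": e.tfidf,
                            "mrho": e.mrho,
                            "bio": e.bio,
                            "negated": e.negated,
                            "support": e.support,
                        }
                    }
                    for e in graph.edges
                ],
            }
        }
        path.write_text(json.dumps(data, indent=1), encoding="utf-8")
    elif fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "nodes.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["uid", "title", "category"])
            for uid in sorted(graph.nodes):
                n = graph.nodes[uid]
                w.writerow([n.uid, n.title, n.category])
        with open(path / "edges.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["source_uid", "target_uid", "verb", "directed", "tfidf",
                 "mrho", "bio", "negated", "support", "provenance"]
            )
            for e in sorted(
                graph.edges, key=lambda e: (e.source_uid, e.target_uid, e.verb_lemma, e.directed)
            ):
                w.writerow(
                    [
                        e.source_uid,
                        e.target_uid,
                        e.verb_lemma,
                        int(e.directed),
                        repr(e.tfidf),
                        repr(e.mrho),
                        repr(e.bio),
                        int(e.negated),
                        e.support,
                        ";".join(f"{d}:{s}" for d, s in e.provenance),
                    ]
                )
    else:
        raise GraphError(f"unknown export format {fmt!r}")


def import_graph_csv(path: str | Path) -> KnowledgeGraph:
    path = Path(path)
    graph = KnowledgeGraph()
    with open(path / "nodes.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            uid = int(row["uid"])
            graph.nodes[uid] = GraphNode(uid, row["title"], row["category"])
    with open(path / "edges.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            provenance = [
                (d, int(s))
                for d, _, s in (p.partition(":") for p in row["provenance"].split(";") if p)
            ]
            graph.edges.append(
                GraphEdge(
                    source_uid=int(row["source_uid"]),
                    target_uid=int(row["target_uid"]),
                    verb_lemma=row["verb"],
                    directed=bool(int(row["directed"])),
                    tfidf=float(row["tfidf"]),
                    mrho=float(row["mrho"]),
                    bio=float(row["bio"]),
                    negated=bool(int(row["negated"])),
                    provenance=provenance,
                )
            )
    return graph
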