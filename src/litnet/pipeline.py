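"""End-to-end pipeline: link -> parse -> extract -> weight -> assemble.

Documents come from a directory of plain-text files or a JSON manifest
(``[{"doc_id": ..., "text": ...}, ...]``).  Remote sources (PubMed
E-utilities, PDF ingestion) are declared as adapter seams only; this
package stays download-free.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

from . import linker as _linker
from .corpus import LinkingCorpus, import_tables
from .graph import KnowledgeGraph, assemble
from .linker import (
    Annotation,
    apply_acronym_overrides,
    detect_spots,
    extract_acronym_defs,
    filter_by_rho,
    score_all,
)
from .relations import (
    DEFAULT_STOPWORDS,
    Triple,
    adjacent_sentence_triples,
    extract_triples,
    filter_bio_verbs,
    orient,
)
from .syntax import SyntacticAnalyzer, segment_and_parse
from .weighting import CorpusStats, VerbDictionary

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


class DocumentSource(Protocol):
    def fetch(self) -> list[Document]: ...


class DirectorySource:
    """One document per *.txt file; the stem is the doc_id."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def fetch(self) -> list[Document]:
        docs = []
        for p in sorted(self.directory.glob("*.txt")):
            docs.append(Document(p.stem, p.read_text(encoding="utf-8")))
        return docs


class ManifestSource:
    """JSON manifest: a list of {doc_id, text} objects."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def fetch(self) -> list[Document]:
        data = json.loads(self.path.read_text(encoding="utf-8"))
        return [Document(d["doc_id"], d["text"]) for d in data]


class PubMedSource:
    """Adapter seam for live PubMed retrieval; intentionally not implemented."""

    def __init__(self, query: str, sort: str = "relevance", top_n: int = 20):
        self.query, self.sort, self.top_n = query, sort, top_n

    def fetch(self) -> list[Document]:
        raise NotImplementedError(
            "live PubMed retrieval is an adapter seam; supply documents as "
            "text files or a JSON manifest"
        )


class PdfSource:
    """Adapter seam for PDF text extraction; intentionally not implemented."""

    def __init__(self, paths: Sequence[str | Path]):
        self.paths = list(paths)

    def fetch(self) -> list[Document]:
        raise NotImplementedError("PDF ingestion is an adapter seam")


def load_documents(source: str | Path) -> list[Document]:
    source = Path(source)
    if source.is_dir():
        return DirectorySource(source).fetch()
    if source.suffix == ".json":
        return ManifestSource(source).fetch()
    raise ConfigurationError(f"unrecognised document source: {source}")


@dataclass
class PipelineConfig:
    documents: list[Document] = field(default_factory=list)
    corpus: LinkingCorpus | None = None
    analyzer: SyntacticAnalyzer | None = None
    rho_threshold: float = 0.3
    strict_bio: bool = False
    bio_cutoff: float = 0.5
    adjacent: bool = True
    dictionary: VerbDictionary | None = None
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    merge_directions: bool = False
    out_dir: Path | None = None

    def validated(self) -> "PipelineConfig":
        if self.corpus is None:
            raise ConfigurationError("no linking corpus configured")
        if self.analyzer is None:
            raise ConfigurationError("no syntactic analyzer configured")
        if not 0.0 <= self.rho_threshold <= 1.0:
            raise ConfigurationError("rho_threshold must lie in [0, 1]")
        return self


@dataclass
class PipelineResult:
    graph: KnowledgeGraph
    annotations: list[Annotation]
    triples: list[Triple]
    stats: CorpusStats


def annotate_document(
    doc: Document, corpus: LinkingCorpus, rho_threshold: float
) -> list[Annotation]:
    """Spot detection, rho scoring, acronym overrides, threshold filter."""
    spots = detect_spots(doc.doc_id, doc.text, corpus)
    scored = score_all(spots, corpus)
    bindings = extract_acronym_defs(doc.doc_id, doc.text, scored)
    overridden = apply_acronym_overrides(scored, bindings)
    return filter_by_rho(overridden, rho_threshold)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full inference chain and optionally write the tables."""
    config = config.validated()
    corpus = config.corpus
    dictionary = config.dictionary or VerbDictionary.default()
    all_annotations: list[Annotation] = []
    all_triples: list[Triple] = []
    for doc in config.documents:
        annotations = annotate_document(doc, corpus, config.rho_threshold)
        all_annotations.extend(annotations)
        sentences = segment_and_parse(doc.text, doc.doc_id, config.analyzer)
        per_sentence = [
            [
                a
                for a in annotations
                if s.char_start <= a.start and a.end <= s.char_end
            ]
            for s in sentences
        ]
        for s, anns in zip(sentences, per_sentence):
            triples = extract_triples(
                s,
                anns,
                doc.text,
                stopwords=config.stopwords,
                nominal_predicates=dictionary.nominal_entries,
            )
            all_triples.extend(orient(t, s) for t in triples)
        if config.adjacent:
            for k in range(1, len(sentences)):
                all_triples.extend(
                    adjacent_sentence_triples(
                        sentences[k - 1],
                        sentences[k],
                        per_sentence[k - 1],
                        per_sentence[k],
                        doc.text,
                        stopwords=config.stopwords,
                    )
                )
    all_triples = filter_bio_verbs(
        all_triples, dictionary, config.strict_bio, config.bio_cutoff
    )
    stats = CorpusStats.from_triples(all_triples, n_documents=len(config.documents))
    graph = assemble(
        all_triples,
        stats,
        corpus,
        dictionary,
        merge_directions=config.merge_directions,
    )
    if config.out_dir is not None:
        _write_tables(config, all_annotations, all_triples, graph)
    return PipelineResult(graph, all_annotations, all_triples, stats)


def _write_tables(config, annotations, triples, graph) -> None:
    from .graph import export_graph

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "papers.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["doc_id", "n_chars"])
        for d in config.documents:
            w.writerow([d.doc_id, len(d.text)])
    with open(out / "annotations.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["doc_id", "start", "end", "surface", "uid", "title", "category", "rho"])
        for row in _linker.annotations_to_rows(annotations, config.corpus):
            w.writerow(list(row.values()))
    with open(out / "edge_candidates.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["doc_id", "sentence_index", "source_uid", "verb_lemma", "target_uid",
             "directed", "negated", "source_rho", "target_rho"]
        )
        for t in triples:
            w.writerow(
                [t.doc_id, t.sentence_index, t.source_uid, t.verb_lemma,
                 t.target_uid, int(t.directed), int(t.negated),
                 t.source_rho, t.target_rho]
            )
    export_graph(graph, "csv", out)
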