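"""Edge weights: tf.idf over documents, mrho from linker confidences, bio.

Every inferred edge e = (a, verb, b) carries three weights:

* ``tf.idf(e, p, P) = tf(e, p) * idf(e, P)`` where ``tf(e, p)`` is the
  edge's occurrence count in document p divided by the total edge
  occurrences in p, and ``idf(e, P) = ln(N / df(e))`` with N the number
  of documents and df(e) the number of documents containing e.  The
  unit of counting is the *edge*, not the word.  An edge's corpus-level
  weight is the sum of its per-document tf.idf values.
* ``mrho(e) = (rho_a * rho_b) / 2`` — half the product of the two
  endpoint annotations' linking confidences; range [0, 0.5].
* ``bio(verb)`` — dissimilarity in [0, 1] between the edge's verb lemma
  and a fixed dictionary of biological verb forms: 0 for a dictionary
  member, otherwise one minus the maximum character-trigram cosine
  similarity against the dictionary.  0 therefore means "biological
  verb" and larger values mean less pertinent.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .syntax import lemmatize_verb

if TYPE_CHECKING:  # pragma: no cover
    from .relations import Triple

logger = logging.getLogger(__name__)


class WeightingError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class EdgeKey:
    """Identity of a network edge: endpoints plus the mediating verb."""

    source_uid: int
    target_uid: int
    verb_lemma: str

    def __post_init__(self) -> None:
        if self.source_uid == self.target_uid:
            raise WeightingError("edge endpoints must differ")


def edge_key(source_uid: int, target_uid: int, verb_lemma: str, directed: bool) -> EdgeKey:
    """Canonical key: undirected edges get sorted endpoints."""
    if not directed and source_uid > target_uid:
        source_uid, target_uid = target_uid, source_uid
    return EdgeKey(source_uid, target_uid, verb_lemma)


# ---------------------------------------------------------------------------
# corpus statistics


@dataclass
class CorpusStats:
    """Per-document edge occurrence counts backing tf.idf."""

    n_documents: int
    counts: dict[str, Counter] = field(default_factory=dict)  # doc -> EdgeKey counts

    @classmethod
    def from_triples(
        cls, triples: Sequence["Triple"], n_documents: int | None = None
    ) -> "CorpusStats":
        counts: dict[str, Counter] = defaultdict(Counter)
        for t in triples:
            counts[t.doc_id][
                edge_key(t.source_uid, t.target_uid, t.verb_lemma, t.directed)
            ] += 1
        n = n_documents if n_documents is not None else len(counts)
        if n < 1:
            n = 1
        return cls(n_documents=n, counts=dict(counts))

    def doc_total(self, doc_id: str) -> int:
        return sum(self.counts.get(doc_id, Counter()).values())

    def doc_frequency(self, e: EdgeKey) -> int:
        return sum(1 for c in self.counts.values() if c.get(e, 0) > 0)

    def documents_with(self, e: EdgeKey) -> list[str]:
        return [d for d, c in self.counts.items() if c.get(e, 0) > 0]


def term_freq(e: EdgeKey, doc_id: str, stats: CorpusStats) -> float:
    total = stats.doc_total(doc_id)
    if total == 0:
        logger.warning("document %r has no edge occurrences; tf undefined -> 0", doc_id)
        return 0.0
    return stats.counts[doc_id].get(e, 0) / total


def inv_doc_freq(e: EdgeKey, stats: CorpusStats) -> float:
    df = stats.doc_frequency(e)
    if df == 0:
        raise WeightingError(f"edge {e} was never observed; idf undefined")
    return math.log(stats.n_documents / df)


def tf_idf(e: EdgeKey, doc_id: str, stats: CorpusStats) -> float:
    return term_freq(e, doc_id, stats) * inv_doc_freq(e, stats)


def corpus_tf_idf(e: EdgeKey, stats: CorpusStats) -> float:
    """Corpus-level weight: sum of tf.idf over documents containing e."""
    return sum(tf_idf(e, d, stats) for d in stats.documents_with(e))


def mrho(rho_a: float, rho_b: float) -> float:
    """Half the product of the endpoint confidences; range [0, 0.5]."""
    for r in (rho_a, rho_b):
        if not 0.0 <= r <= 1.0:
            raise WeightingError(f"rho {r} outside [0, 1]")
    return (rho_a * rho_b) / 2


# ---------------------------------------------------------------------------
# biological-verb dictionary

#: the packaged default dictionary of biological verb forms
DEFAULT_VERBS_RESOURCE = "bio_verbs.txt"


def _trigrams(s: str) -> Counter:
    padded = f"^{s}$"
    if len(padded) < 3:
        return Counter({padded: 1})
    return Counter(padded[i : i + 3] for i in range(len(padded) - 2))


def _cosine(a: Counter, b: Counter) -> float:
    dot = sum(v * b[k] for k, v in a.items())
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return dot / (na * nb)


@dataclass
class VerbDictionary:
    """Lemmatized biological relation words plus a trigram vector space.

    Most entries are verbs; nominal relation words (e.g.
    "ubiquitination") are kept as nominal predicates matched against
    noun tokens in root/acl position.
    """

    entries: frozenset[str]
    nominal_entries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.entries:
            raise WeightingError("verb dictionary is empty")
        self._vectors = {e: _trigrams(e) for e in self.entries}

    @classmethod
    def from_forms(cls, forms: Iterable[str]) -> "VerbDictionary":
        entries = set()
        nominals = set()
        for raw in forms:
            form = raw.strip().lower()
            if not form:
                continue
            lemma = lemmatize_verb(form)
            entries.add(lemma)
            if lemma.endswith(("tion", "sis", "ment")):
                nominals.add(lemma)
        return cls(frozenset(entries), frozenset(nominals))

    @classmethod
    def from_file(cls, path: str | Path) -> "VerbDictionary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_forms(lines)

    @classmethod
    def default(cls) -> "VerbDictionary":
        text = (
            resources.files("litnet.data")
            .joinpath(DEFAULT_VERBS_RESOURCE)
            .read_text(encoding="utf-8")
        )
        return cls.from_forms(text.splitlines())

    def max_similarity(self, lemma: str) -> float:
        vec = _trigrams(lemma.lower())
        return max(_cosine(vec, v) for v in self._vectors.values())


def bio_score(verb_lemma: str, dictionary: VerbDictionary) -> float:
    """0 for a dictionary verb; else 1 - max trigram cosine similarity."""
    if not verb_lemma:
        raise WeightingError("empty verb lemma")
    lemma = lemmatize_verb(verb_lemma.lower())
    if lemma in dictionary.entries:
        return 0.0
    return 1.0 - dictionary.max_similarity(lemma)
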