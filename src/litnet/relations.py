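"""Verb-mediated relation extraction from parsed, annotated sentences.

For every pair of distinct entities annotated in one sentence, the
extractor looks for the verb governing both spots in the dependency
tree (the root between the two noun parts).  A candidate triple
<subject, verb, object> is emitted only when both spot heads reach the
verb through an admissible chain of dependency labels (the syntactic
coherence check); pairs joined only through e.g. adverbial clauses are
rejected.  Direction follows grammatical voice: the nsubj entity points
at the object entity, passive clauses are swapped (the by-agent becomes
the source), and when neither entity is a subject the edge is
undirected.  A restricted adjacent-sentence rule links the single
entity of sentence i to entities of sentence i+1 when the latter's
root verb has a bare pronoun subject.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

from .linker import Annotation
from .syntax import (
    Sentence,
    SyntaxError_,
    Token,
    is_passive,
    lowest_common_ancestor,
    path_between,
    token_spans,
    verb_between,
)
from .weighting import VerbDictionary, bio_score

#: dependency labels a spot head may traverse to reach its verb
ADMISSIBLE_LABELS = frozenset(
    {"nsubj", "nsubjpass", "dobj", "pobj", "prep", "conj", "appos",
     "compound", "attr", "agent", "dative"}
)

#: POS tags removed before relation extraction (function words, symbols)
PRUNE_POS = frozenset(
    {"DT", "IN", "CC", "TO", "UH", "SYM", "HYPH", "LS", "NFP", "ADD", "AFX"}
)

DEFAULT_STOPWORDS = frozenset(
    """the a an this that these those is are was were be been being has have
    had do does did of in on at by with from to for and or but not""".split()
)

_URL_RE = re.compile(r"^(https?://|www\.)\S+$|^\S+@\S+\.\S+$", re.I)

_SUBJECT_LABELS = frozenset({"nsubj", "csubj"})
_PASSIVE_SUBJECT_LABELS = frozenset({"nsubjpass", "csubjpass"})
_OBJECT_LABELS = frozenset(
    {"dobj", "pobj", "attr", "dative", "conj", "appos", "compound", "prep", "agent"}
)


class ExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class Triple:
    """One candidate edge: <source entity, verb lemma, target entity>."""

    doc_id: str
    sentence_index: int
    source_uid: int
    target_uid: int
    verb_lemma: str
    directed: bool = False
    negated: bool = False
    source_rho: float = 0.0
    target_rho: float = 0.0
    source_head: int = -1  # token index of the source spot head
    target_head: int = -1

    def __post_init__(self) -> None:
        if self.source_uid == self.target_uid:
            raise ExtractionError("self-loop triple")
        if not self.verb_lemma or self.verb_lemma != self.verb_lemma.lower():
            raise ExtractionError("verb lemma must be non-empty lowercase")


def prune_tokens(
    sentence: Sentence, stopwords: frozenset[str] = DEFAULT_STOPWORDS
) -> list[Token]:
    """Drop function-word POS, URLs and stop-words; keep nouns and verbs."""
    kept = []
    for t in sentence.tokens:
        if t.pos in PRUNE_POS:
            continue
        if _URL_RE.match(t.text):
            continue
        if not t.is_verb and t.text.lower() in stopwords:
            continue
        kept.append(t)
    return kept


def _survives_prune(tok: Token, stopwords: frozenset[str]) -> bool:
    if tok.pos in PRUNE_POS or _URL_RE.match(tok.text):
        return False
    return tok.is_verb or tok.text.lower() not in stopwords


def annotation_head(
    sentence: Sentence, spans: list[tuple[int, int]], ann: Annotation
) -> int | None:
    """Token index of the spot head: the covered token whose head is outside."""
    covered = [
        k for k, (s, e) in enumerate(spans) if s >= ann.start and e <= ann.end
    ]
    if not covered:
        return None
    cov = set(covered)
    for k in covered:
        if sentence.tokens[k].head not in cov or sentence.tokens[k].is_root:
            return k
    return covered[-1]


def _coherent(sentence: Sentence, head: int, verb: Token) -> bool:
    """Every edge between the spot head and the verb bears an admissible label."""
    labels = []
    lca = lowest_common_ancestor(sentence, head, verb.index)
    for endpoint in (head, verb.index):
        cur = endpoint
        while cur != lca:
            if cur != verb.index:
                labels.append(sentence.tokens[cur].dep)
            cur = sentence.tokens[cur].head
    return all(lbl in ADMISSIBLE_LABELS for lbl in labels)


def _role_label(sentence: Sentence, head: int, verb_index: int) -> str:
    """Label of the path edge adjacent to the verb (the entity's role)."""
    path = path_between(sentence, head, verb_index)
    for k, node in enumerate(path):
        if node == verb_index:
            adjacent = path[k - 1] if k > 0 else path[k + 1]
            return sentence.tokens[adjacent].dep
    return sentence.tokens[head].dep


def _is_negated(sentence: Sentence, verb: Token) -> bool:
    return any(c.dep == "neg" for c in sentence.children(verb.index))


def extract_triples(
    sentence: Sentence,
    annotations: Sequence[Annotation],
    doc_text: str,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    nominal_predicates: frozenset[str] = frozenset(),
) -> list[Triple]:
    """Candidate triples for every coherent co-sentential entity pair.

    Synonym spots of the same entity (e.g. a long form and its acronym)
    collapse into one triple keeping the higher rho per endpoint.
    """
    if not sentence.tokens:
        raise ExtractionError("sentence has no parse")
    spans = token_spans(sentence, doc_text)
    anns = [
        a for a in annotations if a.start >= sentence.char_start and a.end <= sentence.char_end
    ]
    heads = {}
    for a in anns:
        h = annotation_head(sentence, spans, a)
        if h is not None:
            heads[a] = h
    anns = list(heads)
    best: dict[tuple[int, int, str], Triple] = {}
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            a, b = anns[i], anns[j]
            if a.uid == b.uid:
                continue
            verb = verb_between(sentence, heads[a], heads[b], nominal_predicates)
            if verb is None or not _survives_prune(verb, stopwords):
                continue
            if not _coherent(sentence, heads[a], verb) or not _coherent(
                sentence, heads[b], verb
            ):
                continue
            first, second = (a, b) if a.start <= b.start else (b, a)
            triple = Triple(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                source_uid=first.uid,
                target_uid=second.uid,
                verb_lemma=verb.lemma.lower(),
                directed=False,
                negated=_is_negated(sentence, verb),
                source_rho=first.rho,
                target_rho=second.rho,
                source_head=heads[first],
                target_head=heads[second],
            )
            key = (
                min(triple.source_uid, triple.target_uid),
                max(triple.source_uid, triple.target_uid),
                triple.verb_lemma,
            )
            prev = best.get(key)
            if prev is None:
                best[key] = triple
            else:
                best[key] = replace(
                    prev,
                    source_rho=max(prev.source_rho, triple.source_rho),
                    target_rho=max(prev.target_rho, triple.target_rho),
                )
    return list(best.values())


def orient(triple: Triple, sentence: Sentence) -> Triple:
    """Set edge direction from grammatical voice and argument roles.

    Active clause: nsubj entity -> object entity.  Passive clause: the
    nsubjpass entity is the target, the agent/pobj entity the source.
    With no subject among the pair the edge stays undirected, endpoints
    in sentence order.  Idempotent.
    """
    if triple.source_head < 0 or triple.target_head < 0:
        return triple
    verb = verb_between(
        sentence,
        triple.source_head,
        triple.target_head,
        frozenset({triple.verb_lemma}),
    )
    if verb is None:
        return triple
    role_src = _role_label(sentence, triple.source_head, verb.index)
    role_tgt = _role_label(sentence, triple.target_head, verb.index)
    passive = verb.is_verb and is_passive(verb, sentence)

    def swapped() -> Triple:
        return replace(
            triple,
            source_uid=triple.target_uid,
            target_uid=triple.source_uid,
            source_rho=triple.target_rho,
            target_rho=triple.source_rho,
            source_head=triple.target_head,
            target_head=triple.source_head,
            directed=True,
        )

    if passive:
        if role_src in _PASSIVE_SUBJECT_LABELS:
            return swapped()
        if role_tgt in _PASSIVE_SUBJECT_LABELS:
            return replace(triple, directed=True)
        return replace(triple, directed=False)
    if role_src in _SUBJECT_LABELS and role_tgt not in _SUBJECT_LABELS:
        return replace(triple, directed=True)
    if role_tgt in _SUBJECT_LABELS and role_src not in _SUBJECT_LABELS:
        return swapped()
    return replace(triple, directed=False)


def adjacent_sentence_triples(
    prev: Sentence,
    cur: Sentence,
    prev_annotations: Sequence[Annotation],
    cur_annotations: Sequence[Annotation],
    doc_text: str,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[Triple]:
    """Pronoun-bridged triples across a sentence boundary.

    Applies only in the unambiguous case: the current sentence's root
    verb has a personal-pronoun subject and the previous sentence holds
    exactly one annotated entity, which substitutes for the pronoun.
    """
    if prev.index + 1 != cur.index:
        raise ExtractionError(
            f"sentences {prev.index} and {cur.index} are not consecutive"
        )
    prev_uids = {a.uid for a in prev_annotations}
    if len(prev_uids) != 1:
        return []
    antecedent = max(prev_annotations, key=lambda a: a.rho)
    try:
        root = cur.root()
    except SyntaxError_:
        return []
    if not root.is_verb:
        return []
    pronoun = next(
        (
            c
            for c in cur.children(root.index)
            if c.pos == "PRP" and c.dep in ("nsubj", "nsubjpass")
        ),
        None,
    )
    if pronoun is None:
        return []
    spans = token_spans(cur, doc_text)
    triples = []
    for ann in cur_annotations:
        if not (cur.char_start <= ann.start and ann.end <= cur.char_end):
            continue
        if ann.uid == antecedent.uid:
            continue
        head = annotation_head(cur, spans, ann)
        if head is None:
            continue
        verb = verb_between(cur, pronoun.index, head)
        if verb is None or not _survives_prune(verb, stopwords):
            continue
        if not _coherent(cur, head, verb):
            continue
        t = Triple(
            doc_id=cur.doc_id,
            sentence_index=cur.index,
            source_uid=antecedent.uid,
            target_uid=ann.uid,
            verb_lemma=verb.lemma.lower(),
            negated=_is_negated(cur, verb),
            source_rho=antecedent.rho,
            target_rho=ann.rho,
            source_head=pronoun.index,
            target_head=head,
        )
        triples.append(orient(t, cur))
    return triples


def filter_bio_verbs(
    triples: Sequence[Triple],
    dictionary: VerbDictionary,
    strict: bool,
    cutoff: float = 0.5,
) -> list[Triple]:
    """Strict mode keeps only triples whose bio score is below the cutoff."""
    if not strict:
        return list(triples)
    return [t for t in triples if bio_score(t.verb_lemma, dictionary) < cutoff]
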