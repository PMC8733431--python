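"""Deterministic test fixtures: mini-corpora, documents with gold answers.

Two kinds of fixture are provided:

* the packaged *worked example*: a real literature sentence about the
  CD147/Basigin gene with a hand-built dependency parse and a micro
  gazetteer (BSG with synonym CD147, VEGFA with synonym VEGF, PGF with
  synonyms PLGF and "placental growth factor");
* a seeded synthetic generator that emits mini-ontologies and documents
  composed from sentence templates with exact gold annotations, gold
  oriented triples, and matching hand-template dependency parses.  The
  templates jointly exercise every dependency pattern the extractor
  admits (subject, passive subject + agent, direct object, prepositional
  object, conjunct chains, appositions, noun compounds, attributes,
  datives) plus the pronoun-bridged adjacent-sentence rule.

All randomness sits behind one ``random.Random(seed)``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import EntityPage, LinkingCorpus, OntologyRecord, build_corpus
from .pipeline import Document
from .syntax import Sentence, Token

BIO_TEMPLATE_VERBS = (
    "regulate", "activate", "induce", "increase", "block",
    "stimulate", "trigger", "control", "reduce", "enhance",
)

#: verbs deliberately far from the biological dictionary
DISTRACTOR_VERBS = ("resemble", "concern", "precede", "accompany")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_entities_per_category: int = 6
    synonyms_per_entity: int = 1
    n_documents: int = 20
    sentences_per_document: int = 4
    planted_triple_density: float = 0.9
    distractor_verb_rate: float = 0.0
    ambiguous_surface_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_entities_per_category", "synonyms_per_entity",
                     "n_documents", "sentences_per_document"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        for name in ("planted_triple_density", "distractor_verb_rate",
                     "ambiguous_surface_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise FixtureError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# the packaged worked example

WORKED_EXAMPLE_SENTENCE = (
    "CD147 regulates several VEGF isoforms and placental growth factor "
    "(PLGF), and it has unique effects on trophoblastic function."
)

_WE_TOKENS = [
    # (text, lemma, pos, dep, head)
    ("CD147", "cd147", "NNP", "nsubj", 1),
    ("regulates", "regulate", "VBZ", "ROOT", 1),
    ("several", "several", "JJ", "amod", 4),
    ("VEGF", "vegf", "NNP", "compound", 4),
    ("isoforms", "isoform", "NNS", "dobj", 1),
    ("and", "and", "CC", "cc", 4),
    ("placental", "placental", "JJ", "amod", 8),
    ("growth", "growth", "NN", "compound", 8),
    ("factor", "factor", "NN", "conj", 4),
    ("(", "(", "X", "punct", 10),
    ("PLGF", "plgf", "NNP", "appos", 8),
    (")", ")", "X", "punct", 10),
    (",", ",", "X", "punct", 1),
    ("and", "and", "CC", "cc", 1),
    ("it", "it", "PRP", "nsubj", 15),
    ("has", "have", "VBZ", "conj", 1),
    ("unique", "unique", "JJ", "amod", 17),
    ("effects", "effect", "NNS", "dobj", 15),
    ("on", "on", "IN", "prep", 17),
    ("trophoblastic", "trophoblastic", "JJ", "amod", 20),
    ("function", "function", "NN", "pobj", 18),
    (".", ".", "X", "punct", 1),
]


def worked_example_corpus() -> LinkingCorpus:
    """The micro gazetteer behind the packaged example sentence."""
    corpus = LinkingCorpus()
    corpus.pages = {
        1: EntityPage(1, "BSG", "Genes", "basigin (EMMPRIN); OK blood group"),
        2: EntityPage(2, "VEGFA", "Genes", "vascular endothelial growth factor A"),
        3: EntityPage(3, "PGF", "Genes", "placental growth factor"),
    }
    corpus.redirects = {
        "CD147": 1,
        "VEGF": 2,
        "PLGF": 3,
        "placental growth factor": 3,
    }
    corpus.pagelinks = {(1, 2), (1, 3)}
    corpus.validate()
    return corpus


def worked_example_document() -> Document:
    return Document("worked-example", WORKED_EXAMPLE_SENTENCE)


def worked_example_parse(doc_id: str = "worked-example") -> list[Sentence]:
    tokens = [
        Token(k, text, lemma, pos, dep, head)
        for k, (text, lemma, pos, dep, head) in enumerate(_WE_TOKENS)
    ]
    return [Sentence(doc_id, 0, 0, len(WORKED_EXAMPLE_SENTENCE), tokens)]


#: the two gold edges of the worked example: (source, verb, target, directed)
WORKED_EXAMPLE_GOLD = frozenset(
    {(1, "regulate", 2, True), (1, "regulate", 3, True)}
)


# ---------------------------------------------------------------------------
# synthetic corpus


def make_mini_corpus(spec: FixtureSpec) -> tuple[LinkingCorpus, dict[str, int]]:
    """Seeded mini gazetteer over Genes/Diseases/Drugs categories.

    Returns the corpus and a gold surface->uid map (titles and
    synonyms, including the losing side of any planted ambiguity).
    """
    rng = random.Random(spec.seed)
    categories = (("Genes", "GEN"), ("Diseases", "DIS"), ("Drugs", "DRG"))
    records = []
    gold: dict[str, int] = {}
    names_by_cat: dict[str, list[str]] = {}
    for cat, prefix in categories:
        names = [f"{prefix}{i:02d}" for i in range(1, spec.n_entities_per_category + 1)]
        names_by_cat[cat] = names
        for i, name in enumerate(names):
            synonyms = [
                f"{name.lower()}syn{j}" for j in range(spec.synonyms_per_entity)
            ]
            if (
                spec.ambiguous_surface_rate > 0
                and i + 1 < len(names)
                and rng.random() < spec.ambiguous_surface_rate
            ):
                synonyms.append(f"amb{prefix.lower()}{i}")
            links = [f"{prefix}:{i + 2:03d}"] if i + 1 < len(names) else []
            records.append(
                OntologyRecord(
                    source_id=f"{prefix}:{i + 1:03d}",
                    name=name,
                    synonyms=tuple(synonyms),
                    category=cat,
                    links=tuple(links),
                )
            )
            if (
                spec.ambiguous_surface_rate > 0
                and i > 0
                and f"amb{prefix.lower()}{i - 1}"
                in records[-2].synonyms
            ):
                records[-1] = OntologyRecord(
                    source_id=records[-1].source_id,
                    name=records[-1].name,
                    synonyms=records[-1].synonyms + (f"amb{prefix.lower()}{i - 1}",),
                    category=cat,
                    links=records[-1].links,
                )
    corpus = build_corpus(records)
    title_to_uid = {p.title: p.uid for p in corpus.pages.values()}
    for rec in records:
        uid = title_to_uid[rec.name]
        gold[rec.name] = uid
        for syn in rec.synonyms:
            gold.setdefault(syn, corpus.redirects.get(syn, uid))
    return corpus, gold


# ---------------------------------------------------------------------------
# sentence templates


@dataclass
class SentenceFixture:
    words: list[str]
    tokens: list[tuple[str, str, str, str, int]]  # text, lemma, pos, dep, head
    mentions: list[tuple[int, int]]  # (token index, uid)
    gold: list[tuple[int, str, int, bool]] = field(default_factory=list)
    distractor: bool = False


def _third_person(verb: str) -> str:
    return verb + ("es" if verb.endswith(("s", "x", "z", "ch", "sh")) else "s")


def _past(verb: str) -> str:
    return verb + ("d" if verb.endswith("e") else "ed")


def _t_active(a, b, ua, ub, verb, distractor=False) -> SentenceFixture:
    v = _third_person(verb)
    return SentenceFixture(
        words=[a, v, b, "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            (v, verb, "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "dobj", 1),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (2, ub)],
        gold=[(ua, verb, ub, True)],
        distractor=distractor,
    )


def _t_passive(a, b, ua, ub, verb) -> SentenceFixture:
    v = _past(verb)
    return SentenceFixture(
        words=[b, "is", v, "by", a, "."],
        tokens=[
            (b, b.lower(), "NNP", "nsubjpass", 2),
            ("is", "be", "VBZ", "auxpass", 2),
            (v, verb, "VBN", "ROOT", 2),
            ("by", "by", "IN", "agent", 2),
            (a, a.lower(), "NNP", "pobj", 3),
            (".", ".", "X", "punct", 2),
        ],
        mentions=[(0, ub), (4, ua)],
        gold=[(ua, verb, ub, True)],
    )


def _t_compound(a, b, ua, ub, verb) -> SentenceFixture:
    v = _third_person(verb)
    return SentenceFixture(
        words=[a, v, b, "protein", "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            (v, verb, "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "compound", 3),
            ("protein", "protein", "NN", "dobj", 1),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (2, ub)],
        gold=[(ua, verb, ub, True)],
    )


def _t_conj(a, b, c, ua, ub, uc, verb) -> SentenceFixture:
    v = _third_person(verb)
    return SentenceFixture(
        words=[a, v, b, "and", c, "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            (v, verb, "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "dobj", 1),
            ("and", "and", "CC", "cc", 2),
            (c, c.lower(), "NNP", "conj", 2),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (2, ub), (4, uc)],
        gold=[(ua, verb, ub, True), (ua, verb, uc, True)],
    )


def _t_appos(a, b, bsyn, ua, ub, verb) -> SentenceFixture:
    v = _third_person(verb)
    return SentenceFixture(
        words=[a, v, b, "(", bsyn, ")", "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            (v, verb, "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "dobj", 1),
            ("(", "(", "X", "punct", 4),
            (bsyn, bsyn.lower(), "NNP", "appos", 2),
            (")", ")", "X", "punct", 4),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (2, ub), (4, ub)],
        gold=[(ua, verb, ub, True)],
    )


def _t_prep(a, b, ua, ub) -> SentenceFixture:
    return SentenceFixture(
        words=[a, "interacts", "with", b, "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            ("interacts", "interact", "VBZ", "ROOT", 1),
            ("with", "with", "IN", "prep", 1),
            (b, b.lower(), "NNP", "pobj", 2),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (3, ub)],
        gold=[(ua, "interact", ub, True)],
    )


def _t_attr(a, b, ua, ub) -> SentenceFixture:
    return SentenceFixture(
        words=[a, "is", "a", "regulator", "of", b, "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            ("is", "be", "VBZ", "ROOT", 1),
            ("a", "a", "DT", "det", 3),
            ("regulator", "regulator", "NN", "attr", 1),
            ("of", "of", "IN", "prep", 3),
            (b, b.lower(), "NNP", "pobj", 4),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (5, ub)],
        gold=[(ua, "be", ub, True)],
    )


def _t_dative(a, b, ua, ub) -> SentenceFixture:
    return SentenceFixture(
        words=[a, "gives", b, "resistance", "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubj", 1),
            ("gives", "give", "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "dative", 1),
            ("resistance", "resistance", "NN", "dobj", 1),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(0, ua), (2, ub)],
        gold=[(ua, "give", ub, True)],
    )


def _t_undirected(a, b, ua, ub) -> SentenceFixture:
    return SentenceFixture(
        words=["The", "study", "links", a, "with", b, "."],
        tokens=[
            ("The", "the", "DT", "det", 1),
            ("study", "study", "NN", "nsubj", 2),
            ("links", "link", "VBZ", "ROOT", 2),
            (a, a.lower(), "NNP", "dobj", 2),
            ("with", "with", "IN", "prep", 2),
            (b, b.lower(), "NNP", "pobj", 4),
            (".", ".", "X", "punct", 2),
        ],
        mentions=[(3, ua), (5, ub)],
        gold=[(ua, "link", ub, False)],
    )


def _t_pronoun_prev(a, ua) -> SentenceFixture:
    return SentenceFixture(
        words=[a, "is", "overexpressed", "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubjpass", 2),
            ("is", "be", "VBZ", "auxpass", 2),
            ("overexpressed", "overexpress", "VBN", "ROOT", 2),
            (".", ".", "X", "punct", 2),
        ],
        mentions=[(0, ua)],
    )


def _t_pronoun_cur(b, ub, ua, verb) -> SentenceFixture:
    v = _third_person(verb)
    return SentenceFixture(
        words=["It", v, b, "."],
        tokens=[
            ("It", "it", "PRP", "nsubj", 1),
            (v, verb, "VBZ", "ROOT", 1),
            (b, b.lower(), "NNP", "dobj", 1),
            (".", ".", "X", "punct", 1),
        ],
        mentions=[(2, ub)],
        gold=[(ua, verb, ub, True)],
    )


def _t_filler(a, ua) -> SentenceFixture:
    return SentenceFixture(
        words=[a, "was", "studied", "in", "detail", "."],
        tokens=[
            (a, a.lower(), "NNP", "nsubjpass", 2),
            ("was", "be", "VBD", "auxpass", 2),
            ("studied", "study", "VBN", "ROOT", 2),
            ("in", "in", "IN", "prep", 2),
            ("detail", "detail", "NN", "pobj", 3),
            (".", ".", "X", "punct", 2),
        ],
        mentions=[(0, ua)],
    )


_NO_SPACE_BEFORE = {".", ",", ")"}
_NO_SPACE_AFTER = {"("}


def _join(words: list[str], offset: int) -> tuple[str, list[tuple[int, int]]]:
    text = ""
    spans = []
    for w in words:
        if text and w not in _NO_SPACE_BEFORE and not text.endswith("("):
            text += " "
        spans.append((offset + len(text), offset + len(text) + len(w)))
        text += w
    return text, spans


# ---------------------------------------------------------------------------
# document generation


@dataclass
class DocumentFixture:
    document: Document
    sentences: list[Sentence]
    gold_annotations: list[tuple[int, int, int]]  # (start, end, uid)
    gold_triples: set[tuple[int, str, int, bool]]
    distractor_triples: set[tuple[int, str, int, bool]]


def make_documents(spec: FixtureSpec, corpus: LinkingCorpus) -> list[DocumentFixture]:
    """Generate documents + parses + gold answers from the templates."""
    rng = random.Random(spec.seed + 1)
    titles = sorted(
        (p.title, p.uid) for p in corpus.pages.values()
    )
    synonyms_of: dict[int, list[str]] = {}
    for surf, uid in sorted(corpus.redirects.items()):
        if not surf.startswith("amb"):
            synonyms_of.setdefault(uid, []).append(surf)

    def pick_entities(k: int) -> list[tuple[str, int]]:
        return rng.sample(titles, k)

    fixtures = []
    for d in range(spec.n_documents):
        doc_id = f"doc{d:03d}"
        sent_fixtures: list[SentenceFixture] = []
        slots = spec.sentences_per_document
        while slots > 0:
            plant = rng.random() < spec.planted_triple_density
            if not plant:
                (a, ua), = pick_entities(1)
                sent_fixtures.append(_t_filler(a, ua))
                slots -= 1
                continue
            if rng.random() < spec.distractor_verb_rate:
                (a, ua), (b, ub) = pick_entities(2)
                verb = rng.choice(DISTRACTOR_VERBS)
                sent_fixtures.append(_t_active(a, b, ua, ub, verb, distractor=True))
                slots -= 1
                continue
            verb = rng.choice(BIO_TEMPLATE_VERBS)
            choice = rng.randrange(10) if slots >= 2 else rng.randrange(9)
            if choice == 0:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_active(a, b, ua, ub, verb))
            elif choice == 1:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_passive(a, b, ua, ub, verb))
            elif choice == 2:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_compound(a, b, ua, ub, verb))
            elif choice == 3:
                (a, ua), (b, ub), (c, uc) = pick_entities(3)
                sent_fixtures.append(_t_conj(a, b, c, ua, ub, uc, verb))
            elif choice == 4:
                (a, ua), (b, ub) = pick_entities(2)
                syns = synonyms_of.get(ub)
                if syns:
                    sent_fixtures.append(_t_appos(a, b, rng.choice(syns), ua, ub, verb))
                else:
                    sent_fixtures.append(_t_active(a, b, ua, ub, verb))
            elif choice == 5:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_prep(a, b, ua, ub))
            elif choice == 6:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_dative(a, b, ua, ub))
            elif choice == 7:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_undirected(a, b, ua, ub))
            elif choice == 8:
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_attr(a, b, ua, ub))
            else:  # pronoun-bridged pair, occupies two slots
                (a, ua), (b, ub) = pick_entities(2)
                sent_fixtures.append(_t_pronoun_prev(a, ua))
                sent_fixtures.append(_t_pronoun_cur(b, ub, ua, verb))
                slots -= 1
            slots -= 1
        fixtures.append(_realize(doc_id, sent_fixtures))
    return fixtures


def _realize(doc_id: str, sent_fixtures: list[SentenceFixture]) -> DocumentFixture:
    text = ""
    sentences = []
    gold_annotations = []
    gold_triples: set = set()
    distractor_triples: set = set()
    for idx, sf in enumerate(sent_fixtures):
        if text:
            text += " "
        start = len(text)
        sent_text, spans = _join(sf.words, start)
        text += sent_text
        tokens = [
            Token(k, t, lemma, pos, dep, head)
            for k, (t, lemma, pos, dep, head) in enumerate(sf.tokens)
        ]
        sentences.append(Sentence(doc_id, idx, start, len(text), tokens))
        for token_index, uid in sf.mentions:
            s, e = spans[token_index]
            gold_annotations.append((s, e, uid))
        target = distractor_triples if sf.distractor else gold_triples
        for src, verb, tgt, directed in sf.gold:
            if directed:
                target.add((src, verb, tgt, True))
            else:
                target.add((min(src, tgt), verb, max(src, tgt), False))
    return DocumentFixture(
        document=Document(doc_id, text),
        sentences=sentences,
        gold_annotations=gold_annotations,
        gold_triples=gold_triples,
        distractor_triples=distractor_triples,
    )


def triple_key(t) -> tuple[int, str, int, bool]:
    """Canonical comparison key for a Triple (undirected pairs sorted)."""
    if t.directed:
        return (t.source_uid, t.verb_lemma, t.target_uid, True)
    return (
        min(t.source_uid, t.target_uid),
        t.verb_lemma,
        max(t.source_uid, t.target_uid),
        False,
    )
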