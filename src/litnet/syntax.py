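"""Sentence segmentation, POS/dependency annotation and tree queries.

Dependency analysis is a pluggable seam: any object with a
``parse(text) -> list[Sentence]`` method can drive the pipeline.
Three analyzers are bundled:

* :class:`FixtureAnalyzer` — replays hand-written parses from the JSON
  fixture format (the deterministic path used by tests and by the
  packaged worked example);
* :class:`RuleBasedSegmenter` — abbreviation-aware sentence splitting
  with no dependency labels, for segmentation-only work;
* :class:`HeuristicAnalyzer` — a deterministic lexicon + pattern
  annotator for simple declarative biomedical prose (subject — verb —
  objects, passives, prepositional attachment).  It is not a trained
  parser; for production-grade parses inject a pretrained statistical
  parser through the same seam.

Tag inventories are Penn-Treebank POS tags and ClearNLP-style
dependency labels, with ``X`` as the catch-all POS.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

POS_TAGS = frozenset(
    """ADD AFX CC CD DT EX FW HYPH IN JJ JJR JJS LS MD NFP NN NNP NNPS NNS
    PDT POS PRP PRP$ RB RBR RBS RP SYM TO UH VB VBD VBG VBN VBP VBZ WDT WP
    WP$ WRB X""".split()
)

DEP_LABELS = frozenset(
    """acl acomp advcl advmod agent amod appos attr aux auxpass case cc ccomp
    compound conj csubj csubjpass dative dep det dobj expl intj mark meta neg
    nmod npadvmod nsubj nsubjpass nummod oprd parataxis pcomp pobj poss
    preconj predet prep prt punct quantmod relcl xcomp ROOT root""".split()
)

VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"})


class SyntaxError_(ValueError):
    """Invalid token annotations or tree structure."""


@dataclass(frozen=True)
class Token:
    """One labelled token: (text, lemma, POS tag, dependency label, head)."""

    index: int
    text: str
    lemma: str
    pos: str
    dep: str
    head: int

    @property
    def is_verb(self) -> bool:
        return self.pos in VERB_TAGS

    @property
    def is_root(self) -> bool:
        return self.head == self.index


@dataclass
class Sentence:
    doc_id: str
    index: int
    char_start: int
    char_end: int
    tokens: list[Token] = field(default_factory=list)

    def root(self) -> Token:
        for t in self.tokens:
            if t.is_root:
                return t
        raise SyntaxError_(f"sentence {self.index} of {self.doc_id} has no root")

    def children(self, index: int) -> list[Token]:
        return [t for t in self.tokens if t.head == index and t.index != index]


def validate_sentence(sentence: Sentence) -> None:
    """Enforce the token contract: known tags, acyclic head chains."""
    n = len(sentence.tokens)
    for t in sentence.tokens:
        where = f"sentence {sentence.index}, token {t.index} ({t.text!r})"
        if t.pos not in POS_TAGS:
            raise SyntaxError_(f"{where}: unknown POS tag {t.pos!r}")
        if t.dep not in DEP_LABELS:
            raise SyntaxError_(f"{where}: unknown dependency label {t.dep!r}")
        if not (0 <= t.head < n):
            raise SyntaxError_(f"{where}: head {t.head} out of range")
    for t in sentence.tokens:
        seen = set()
        cur = t.index
        while not sentence.tokens[cur].is_root:
            if cur in seen:
                raise SyntaxError_(
                    f"sentence {sentence.index}, token {t.index}: head cycle"
                )
            seen.add(cur)
            cur = sentence.tokens[cur].head


class SyntacticAnalyzer(Protocol):
    def parse(self, text: str, doc_id: str = "") -> list[Sentence]: ...


def segment_and_parse(doc_text: str, doc_id: str, analyzer: SyntacticAnalyzer) -> list[Sentence]:
    """Run the analyzer and validate every sentence against the contract."""
    if not doc_text.strip():
        return []
    sentences = analyzer.parse(doc_text, doc_id=doc_id)
    for s in sentences:
        s.doc_id = doc_id
        validate_sentence(s)
    return sentences


# ---------------------------------------------------------------------------
# tree queries


def _path_to_root(sentence: Sentence, i: int) -> list[int]:
    path = [i]
    while not sentence.tokens[path[-1]].is_root:
        path.append(sentence.tokens[path[-1]].head)
    return path


def lowest_common_ancestor(sentence: Sentence, i: int, j: int) -> int:
    pi = _path_to_root(sentence, i)
    pj = set(_path_to_root(sentence, j))
    for node in pi:
        if node in pj:
            return node
    raise SyntaxError_("tokens share no ancestor (malformed tree)")


def path_between(sentence: Sentence, i: int, j: int) -> list[int]:
    """Token indices on the undirected head-path from i to j, inclusive."""
    lca = lowest_common_ancestor(sentence, i, j)
    pi = _path_to_root(sentence, i)
    pj = _path_to_root(sentence, j)
    up = pi[: pi.index(lca) + 1]
    down = pj[: pj.index(lca)]
    return up + list(reversed(down))


def path_edge_labels(sentence: Sentence, i: int, j: int) -> list[str]:
    """Dependency labels of the tree edges on the path between i and j."""
    lca = lowest_common_ancestor(sentence, i, j)
    labels = []
    for endpoint in (i, j):
        cur = endpoint
        while cur != lca:
            labels.append(sentence.tokens[cur].dep)
            cur = sentence.tokens[cur].head
    return labels


def verb_between(
    sentence: Sentence,
    i: int,
    j: int,
    nominal_predicates: frozenset[str] | set[str] = frozenset(),
) -> Token | None:
    """The verb governing tokens i and j, if one exists.

    Returns the lowest common ancestor when it is a verb, otherwise the
    verb on the head-path between i and j nearest to the LCA, otherwise
    None.  ``nominal_predicates`` admits nominal relation words (e.g.
    "ubiquitination") at the root/acl position as verb substitutes.
    """
    n = len(sentence.tokens)
    if i == j or not (0 <= i < n) or not (0 <= j < n):
        raise SyntaxError_(f"invalid token indices ({i}, {j})")

    def acceptable(tok: Token) -> bool:
        if tok.is_verb:
            return True
        return (
            tok.lemma.lower() in nominal_predicates
            and tok.dep in ("ROOT", "root", "acl")
        )

    lca = lowest_common_ancestor(sentence, i, j)
    if acceptable(sentence.tokens[lca]):
        return sentence.tokens[lca]
    path = path_between(sentence, i, j)
    interior = [k for k in path if k not in (i, j)]
    # nearest to the LCA, ties to the smaller index: symmetric in (i, j)
    dist = {k: abs(path.index(k) - path.index(lca)) for k in interior}
    for k in sorted(interior, key=lambda k: (dist[k], k)):
        if acceptable(sentence.tokens[k]):
            return sentence.tokens[k]
    return None


def is_passive(verb: Token, sentence: Sentence) -> bool:
    """Passive voice: the verb has an auxpass or nsubjpass dependent."""
    if not verb.is_verb:
        raise SyntaxError_(f"token {verb.index} ({verb.text!r}) is not a verb")
    return any(
        c.dep in ("auxpass", "nsubjpass") for c in sentence.children(verb.index)
    )


def token_spans(sentence: Sentence, doc_text: str) -> list[tuple[int, int]]:
    """Char offsets of each token, aligned left-to-right within the sentence."""
    spans = []
    cursor = sentence.char_start
    for t in sentence.tokens:
        found = doc_text.find(t.text, cursor, sentence.char_end)
        if found < 0:
            raise SyntaxError_(
                f"token {t.text!r} not found in sentence {sentence.index}"
            )
        spans.append((found, found + len(t.text)))
        cursor = found + len(t.text)
    return spans


# ---------------------------------------------------------------------------
# parse-fixture JSON


def sentences_to_json(sentences: Sequence[Sentence]) -> dict:
    return {
        "sentences": [
            {
                "char_start": s.char_start,
                "char_end": s.char_end,
                "tokens": [
                    {
                        "text": t.text,
                        "lemma": t.lemma,
                        "pos": t.pos,
                        "dep": t.dep,
                        "head": t.head,
                    }
                    for t in s.tokens
                ],
            }
            for s in sentences
        ]
    }


def sentences_from_json(data: dict, doc_id: str = "") -> list[Sentence]:
    sentences = []
    for idx, s in enumerate(data["sentences"]):
        tokens = [
            Token(
                index=k,
                text=t["text"],
                lemma=t["lemma"],
                pos=t["pos"],
                dep=t["dep"],
                head=t["head"],
            )
            for k, t in enumerate(s["tokens"])
        ]
        sentences.append(
            Sentence(doc_id, idx, s["char_start"], s["char_end"], tokens)
        )
    return sentences


def dump_parse_fixture(sentences: Sequence[Sentence], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(sentences_to_json(sentences), indent=1), encoding="utf-8"
    )


def load_parse_fixture(path: str | Path, doc_id: str = "") -> list[Sentence]:
    return sentences_from_json(
        json.loads(Path(path).read_text(encoding="utf-8")), doc_id
    )


class FixtureAnalyzer:
    """Replays pre-computed parses keyed by doc_id (parser-free path)."""

    def __init__(self, parses: dict[str, list[Sentence]]):
        self._parses = parses

    def parse(self, text: str, doc_id: str = "") -> list[Sentence]:
        if doc_id not in self._parses:
            raise SyntaxError_(f"no parse fixture for document {doc_id!r}")
        return self._parses[doc_id]


# ---------------------------------------------------------------------------
# rule-based analyzers

_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "etc", "fig", "figs", "vs", "cf", "dr", "no",
    "approx", "ca",
}

_SENT_BOUNDARY = re.compile(r"[.!?]")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Abbreviation-aware sentence spans (char offsets, half-open)."""
    spans = []
    start = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in ".!?":
            before = text[:i].rstrip()
            last_word = re.split(r"[\s(]+", before)[-1].lower().rstrip(".")
            nxt = text[i + 1 : i + 3]
            is_abbrev = ch == "." and (
                last_word in _ABBREVIATIONS
                or (len(last_word) == 1 and last_word.isalpha())
                or (nxt[:1].isdigit())
            )
            if not is_abbrev:
                end = i + 1
                seg = text[start:end]
                if seg.strip():
                    s = start + (len(seg) - len(seg.lstrip()))
                    spans.append((s, end))
                start = end
                i = end
                continue
        i += 1
    tail = text[start:]
    if tail.strip():
        s = start + (len(tail) - len(tail.lstrip()))
        spans.append((s, start + len(tail.rstrip())))
    return spans


_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9'_-]*[A-Za-z0-9])?|[^\sA-Za-z0-9]")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """(text, start, end) word tokens; hyphens stay inside tokens."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class RuleBasedSegmenter:
    """Segmentation-only fallback: flat trees, no dependency labels."""

    def parse(self, text: str, doc_id: str = "") -> list[Sentence]:
        sentences = []
        for idx, (s, e) in enumerate(split_sentences(text)):
            toks = []
            for k, (t, a, b) in enumerate(tokenize(text[s:e])):
                toks.append(Token(k, t, t.lower(), "X", "dep" if k else "ROOT", 0))
            sentences.append(Sentence(doc_id, idx, s, e, toks))
        return sentences


def lemmatize_verb(form: str) -> str:
    """Heuristic English verb lemmatizer (regular inflections only)."""
    w = form.lower()
    if len(w) > 3 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith("es") and w[-3] in "sxz":
        return w[:-2]
    for suf in ("ches", "shes"):
        if len(w) > len(suf) and w.endswith(suf):
            return w[: -2]
    if len(w) > 2 and w.endswith("s") and not w.endswith("ss"):
        return w[:-1]
    if len(w) > 3 and w.endswith("ied"):
        return w[:-3] + "y"
    if len(w) > 2 and w.endswith("ed"):
        stem = w[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
            return stem[:-1]
        candidate = stem + "e"
        # regulate -> regulated: restoring the silent e is right for
        # -ate/-ce/-se/-ze stems, wrong for e.g. "blocked"
        if stem.endswith(("at", "c", "s", "z", "v", "u", "bl", "gl")):
            return candidate
        return stem
    if len(w) > 4 and w.endswith("ing"):
        stem = w[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
            return stem[:-1]
        if stem.endswith(("at", "c", "s", "z", "v", "u")):
            return stem + "e"
        return stem
    return w


_BE_FORMS = {"is", "are", "was", "were", "be", "been", "being", "am"}
_HAVE_FORMS = {"has", "have", "had"}
_PRONOUNS = {"it", "they", "he", "she", "this", "these", "we", "i", "you"}
_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "several",
                "some", "many", "each", "both", "all", "any", "no"}
_PREPOSITIONS = {"of", "in", "on", "at", "by", "with", "from", "to", "for",
                 "between", "through", "via", "into", "within", "during",
                 "against", "among", "under", "upon"}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_ADJ_SUFFIXES = ("al", "ic", "ous", "ive", "ar", "ary", "ble", "tic", "ent", "ant")


class HeuristicAnalyzer:
    """Deterministic POS + dependency annotation for simple declarative prose.

    Covers the clause shapes the relation extractor consumes: an active
    or passive main verb, a pre-verbal subject, post-verbal objects with
    conjunction chains, prepositional and parenthetical attachment.
    Accuracy degrades on complex embedded clauses; inject a pretrained
    parser for those.
    """

    def __init__(self, verb_lexicon: Iterable[str] = ()):
        base = set(verb_lexicon)
        self._verb_forms: dict[str, str] = {}
        for v in base:
            self._verb_forms[v] = v
            self._verb_forms[v + "s" if not v.endswith(("s", "x", "z")) else v + "es"] = v
            past = v + "d" if v.endswith("e") else v + "ed"
            self._verb_forms[past] = v
            ger = (v[:-1] if v.endswith("e") else v) + "ing"
            self._verb_forms[ger] = v

    def parse(self, text: str, doc_id: str = "") -> list[Sentence]:
        out = []
        for idx, (s, e) in enumerate(split_sentences(text)):
            words = tokenize(text[s:e])
            out.append(self._annotate(words, doc_id, idx, s, e))
        return out

    # -- internals --------------------------------------------------------

    def _pos_of(self, word: str, prev: str | None) -> str:
        lw = word.lower()
        if not word[0].isalnum():
            return "X"
        if lw in _BE_FORMS or lw in _HAVE_FORMS:
            return "VBZ" if lw in ("is", "has") else "VBD" if lw in ("was", "were", "had") else "VBP"
        if lw in _DETERMINERS:
            return "DT"
        if lw in _PREPOSITIONS:
            return "IN"
        if lw in _CONJUNCTIONS:
            return "CC"
        if lw in _PRONOUNS:
            return "PRP"
        if lw in self._verb_forms:
            base = self._verb_forms[lw]
            if lw == base:
                return "VBP"
            if lw.endswith("ing"):
                return "VBG"
            if lw.endswith(("ed", "d")) and lw != base:
                return "VBN" if prev in _BE_FORMS else "VBD"
            return "VBZ"
        if word.isdigit():
            return "CD"
        if word[0].isupper() or any(c.isdigit() for c in word):
            return "NNP"
        if lw.endswith(_ADJ_SUFFIXES):
            return "JJ"
        if lw.endswith("ly"):
            return "RB"
        if lw.endswith("s") and not lw.endswith("ss"):
            return "NNS"
        return "NN"

    def _annotate(self, words, doc_id, idx, char_start, char_end) -> Sentence:
        texts = [w[0] for w in words]
        pos: list[str] = []
        for k, w in enumerate(texts):
            prev = texts[k - 1].lower() if k else None
            pos.append(self._pos_of(w, prev))
        n = len(texts)
        # main verb: first content verb (lexicon or VBN after be); else first verb
        main = None
        for k in range(n):
            if pos[k] in VERB_TAGS and texts[k].lower() not in _BE_FORMS | _HAVE_FORMS:
                main = k
                break
        if main is None:
            for k in range(n):
                if pos[k] in VERB_TAGS:
                    main = k
                    break
        head = [0] * n
        dep = ["dep"] * n
        if main is None:
            main = 0
            dep[0] = "ROOT"
            for k in range(1, n):
                head[k] = 0
        else:
            dep[main] = "ROOT"
            head[main] = main
            passive = pos[main] == "VBN" and any(
                texts[k].lower() in _BE_FORMS for k in range(main)
            )
            self._attach(texts, pos, head, dep, main, passive)
        lemmas = [
            self._verb_forms.get(t.lower(), lemmatize_verb(t.lower()))
            if pos[k] in VERB_TAGS
            else t.lower()
            for k, t in enumerate(texts)
        ]
        tokens = [
            Token(k, texts[k], lemmas[k], pos[k], dep[k], head[k]) for k in range(n)
        ]
        return Sentence(doc_id, idx, char_start, char_end, tokens)

    def _attach(self, texts, pos, head, dep, main, passive) -> None:
        n = len(texts)
        nouny = {"NN", "NNS", "NNP", "NNPS", "PRP", "CD"}
        # pre-verbal region
        subj = None
        for k in range(main - 1, -1, -1):
            if pos[k] in nouny:
                subj = k
                break
        for k in range(main):
            lw = texts[k].lower()
            if k == subj:
                dep[k] = "nsubjpass" if passive else "nsubj"
                head[k] = main
            elif lw in _BE_FORMS and passive:
                dep[k] = "auxpass"
                head[k] = main
            elif pos[k] in VERB_TAGS:
                dep[k] = "aux"
                head[k] = main
            elif pos[k] == "DT":
                dep[k] = "det"
                head[k] = subj if subj is not None else main
            elif pos[k] in ("JJ", "NN", "NNP") and subj is not None and k < subj:
                dep[k] = "amod" if pos[k] == "JJ" else "compound"
                head[k] = subj
            else:
                dep[k] = "dep"
                head[k] = main
        # post-verbal region: objects, preps, conj chains, parentheses
        last_noun = None
        last_prep = None
        first_obj = None
        paren_open = None
        for k in range(main + 1, n):
            lw = texts[k].lower()
            if texts[k] == "(":
                dep[k] = "punct"
                head[k] = min(k + 1, n - 1)
                paren_open = last_noun
                continue
            if texts[k] == ")":
                dep[k] = "punct"
                head[k] = max(k - 1, 0)
                paren_open = None
                continue
            if pos[k] == "X":
                dep[k] = "punct"
                head[k] = main
                continue
            if pos[k] == "IN":
                if passive and lw == "by":
                    dep[k] = "agent"
                else:
                    dep[k] = "prep"
                head[k] = last_noun if (last_noun is not None and lw == "of") else main
                last_prep = k
                continue
            if pos[k] == "CC":
                dep[k] = "cc"
                head[k] = last_noun if last_noun is not None else main
                continue
            if pos[k] == "DT":
                dep[k] = "det"
                head[k] = k + 1 if k + 1 < n else main
                continue
            if pos[k] == "JJ" or (pos[k] == "RB"):
                dep[k] = "amod" if pos[k] == "JJ" else "advmod"
                nxt = next((m for m in range(k + 1, n) if pos[m] in nouny), main)
                head[k] = nxt
                continue
            if pos[k] in nouny:
                nxt = next((m for m in range(k + 1, n) if pos[m] in nouny or pos[m] == "X" or pos[m] in ("CC", "IN")), None)
                if nxt is not None and pos[nxt] in nouny and texts[k + 1 if k + 1 < n else k] not in ("(",) and k + 1 == nxt:
                    dep[k] = "compound"  # noun-noun compound, head right
                    head[k] = nxt
                elif paren_open is not None:
                    dep[k] = "appos"
                    head[k] = paren_open
                elif last_prep is not None and last_prep > (last_noun or -1):
                    dep[k] = "pobj"
                    head[k] = last_prep
                    last_noun = k
                elif last_noun is not None and dep[min(k - 1, n - 1)] == "cc":
                    dep[k] = "conj"
                    head[k] = last_noun
                elif first_obj is None:
                    dep[k] = "dobj"
                    head[k] = main
                    first_obj = k
                    last_noun = k
                else:
                    dep[k] = "dative"
                    head[k] = main
                    last_noun = k
                continue
            dep[k] = "dep"
            head[k] = main
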