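"""Gazetteer entity linking with a commonness/coherence confidence score.

A *spot* is a maximal token n-gram of the document whose surface matches
a corpus page title or synonym redirect.  Each spot is bound to an
entity uid and scored with rho in [0, 1]:

    rho = (commonness + coherence) / 2

where *commonness* is the fraction of corpus surface entries for that
string pointing at the chosen uid (1.0 for an unambiguous surface), and
*coherence* is the mean relatedness between the chosen entity and the
other entities annotated in the same document.  Relatedness between two
entities is 1 when a pagelink joins them (either direction), else the
Jaccard overlap of their pagelink neighbourhoods.  With no other
annotation in the document, rho is the commonness alone.  Annotations
are kept when rho exceeds a user threshold.

Document-local acronym disambiguation: when a sentence defines an
acronym parenthetically after an annotated long form ("placental growth
factor (PLGF)"), later occurrences of the acronym in the same document
are re-bound to the long form's entity, overriding gazetteer matches
(e.g. an acronym that collides with a gene symbol).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from statistics import mean
from typing import Sequence

from .corpus import CASE_SENSITIVE_MAX_LEN, LinkingCorpus, normalize_surface
from .syntax import tokenize

MAX_SPOT_TOKENS = 6


class LinkerError(ValueError):
    pass


@dataclass(frozen=True)
class Annotation:
    """A text span bound to a corpus entity with confidence rho."""

    doc_id: str
    start: int
    end: int
    surface: str
    uid: int
    rho: float = 0.0


@dataclass(frozen=True)
class AcronymBinding:
    doc_id: str
    acronym: str
    uid: int
    defined_at: int


# ---------------------------------------------------------------------------
# spot detection


def _surface_index(corpus: LinkingCorpus) -> dict[str, tuple[int, int]]:
    """normalized surface -> (uid, priority); titles beat redirects."""
    index: dict[str, tuple[int, int]] = {}
    for surf in sorted(corpus.redirects):
        key = normalize_surface(surf)
        index.setdefault(key, (corpus.redirects[surf], 1))
    for uid in sorted(corpus.pages):
        key = normalize_surface(corpus.pages[uid].title)
        index[key] = (uid, 0)  # title wins over any redirect
    return index


def detect_spots(doc_id: str, text: str, corpus: LinkingCorpus) -> list[Annotation]:
    """Match maximal token n-grams against corpus surfaces.

    Longest match wins; ties go to the leftmost; chosen spans never
    overlap.  Matching is case-sensitive for short surfaces (gene
    symbols) and case-insensitive otherwise, mirroring the corpus merge
    policy.
    """
    if not text:
        return []
    index = _surface_index(corpus)
    tokens = [t for t in tokenize(text) if t[0][0].isalnum()]
    candidates: list[tuple[int, int, int, int]] = []  # (-length, start, end, uid)
    for i in range(len(tokens)):
        for n in range(min(MAX_SPOT_TOKENS, len(tokens) - i), 0, -1):
            start = tokens[i][1]
            end = tokens[i + n - 1][2]
            surface = text[start:end]
            hit = index.get(normalize_surface(surface))
            if hit is not None:
                candidates.append((-(end - start), start, end, hit[0]))
    chosen: list[tuple[int, int, int]] = []
    for neg_len, start, end, uid in sorted(candidates):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, uid))
    return [
        Annotation(doc_id, s, e, text[s:e], uid)
        for s, e, uid in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# rho scoring


def relatedness(corpus: LinkingCorpus, x: int, y: int) -> float:
    if x == y or (x, y) in corpus.pagelinks or (y, x) in corpus.pagelinks:
        return 1.0
    nx, ny = corpus.neighbours(x), corpus.neighbours(y)
    union = nx | ny
    if not union:
        return 0.0
    return len(nx & ny) / len(union)


def score_rho(
    ann: Annotation,
    doc_annotations: Sequence[Annotation],
    corpus: LinkingCorpus,
) -> float:
    """Commonness/coherence confidence for one annotation."""
    if ann not in doc_annotations:
        raise LinkerError("annotation is not among the document's annotations")
    cands = corpus.surface_candidates(ann.surface)
    total = sum(cands.values())
    commonness = cands[ann.uid] / total if total else 0.0
    others = {a.uid for a in doc_annotations} - {ann.uid}
    if not others:
        return commonness
    coherence = mean(relatedness(corpus, ann.uid, u) for u in sorted(others))
    return (commonness + coherence) / 2


def score_all(
    annotations: Sequence[Annotation], corpus: LinkingCorpus
) -> list[Annotation]:
    return [
        replace(a, rho=score_rho(a, annotations, corpus)) for a in annotations
    ]


def filter_by_rho(
    annotations: Sequence[Annotation], threshold: float
) -> list[Annotation]:
    """Keep annotations with rho strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise LinkerError(f"threshold {threshold} outside [0, 1]")
    return [a for a in annotations if a.rho > threshold]


# ---------------------------------------------------------------------------
# acronym handling

_ACRONYM_DEF_RE = re.compile(r"\(\s*([A-Z0-9]{2,10})\s*\)")


def _initials_match(long_form: str, acronym: str) -> bool:
    """Word initials of the long form appear in order inside the acronym."""
    initials = [w[0].upper() for w in long_form.split() if w and w[0].isalpha()]
    if not initials or initials[0] != acronym[0].upper():
        return False
    pos = 0
    letters = [c for c in acronym.upper()]
    for init in initials:
        try:
            pos = letters.index(init, pos) + 1
        except ValueError:
            return False
    return True


def extract_acronym_defs(
    doc_id: str, text: str, annotations: Sequence[Annotation]
) -> list[AcronymBinding]:
    """Find "<annotated long form> (<ACR>)" definitions in the document."""
    bindings = []
    by_end = {a.end: a for a in annotations}
    for m in _ACRONYM_DEF_RE.finditer(text):
        acr = m.group(1)
        before = text[: m.start()].rstrip()
        ann = by_end.get(len(before))
        if ann is None or not _initials_match(ann.surface, acr):
            continue
        bindings.append(AcronymBinding(doc_id, acr, ann.uid, m.start(1)))
    return bindings


def apply_acronym_overrides(
    annotations: Sequence[Annotation], bindings: Sequence[AcronymBinding]
) -> list[Annotation]:
    """Re-bind post-definition acronym spots to the long form's entity."""
    if not bindings:
        return list(annotations)
    by_acronym = {b.acronym: b for b in bindings}
    long_form_rho = {
        b.acronym: max(
            (a.rho for a in annotations if a.uid == b.uid and a.end <= b.defined_at),
            default=0.0,
        )
        for b in bindings
    }
    out = []
    for a in annotations:
        b = by_acronym.get(a.surface)
        if b is not None and a.start >= b.defined_at:
            a = replace(a, uid=b.uid, rho=max(a.rho, long_form_rho[a.surface]))
        out.append(a)
    return out


def annotations_to_rows(
    annotations: Sequence[Annotation], corpus: LinkingCorpus
) -> list[dict]:
    """CSV-ready rows (doc_id,start,end,surface,uid,title,category,rho)."""
    rows = []
    for a in annotations:
        page = corpus.pages[a.uid]
        rows.append(
            {
                "doc_id": a.doc_id,
                "start": a.start,
                "end": a.end,
                "surface": a.surface,
                "uid": a.uid,
                "title": page.title,
                "category": page.category,
                "rho": a.rho,
            }
        )
    return rows
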