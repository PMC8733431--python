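"""Build the gazetteer-style linking corpus from ontologies and term tables.

The entity linker does not search ontologies directly.  Each source
(an OBO ontology, or a simple delimited term table exported from a
database) is first converted into a small set of relational tables
modelled on an encyclopedia dump:

* **pages** — one entry per biological element (gene, disease, drug,
  ontology term) with a system-generated integer uid, a title, a
  category and a free-text body;
* **redirects** — one entry per synonym, mapping a surface string to
  the uid of its main page (e.g. ``CD147`` redirects to ``BSG``);
* **pagelinks** — one (uid, uid) tuple per term-to-term relation
  (e.g. ``is_a`` edges), used by the linker's coherence score.

Several sources can be merged into one corpus; collisions between
titles and synonym surfaces are resolved by a deterministic policy
(title beats redirect, earlier source beats later) and logged.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import obonet

logger = logging.getLogger(__name__)

#: titles at or below this length are matched case-sensitively
#: (short gene symbols such as BSG / bsg are case-significant)
CASE_SENSITIVE_MAX_LEN = 5


class CorpusError(ValueError):
    """Raised for malformed source files or broken corpus invariants."""


@dataclass(frozen=True)
class OntologyRecord:
    """One term from an ontology or database source, pre-conversion."""

    source_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    category: str = ""
    description: str = ""
    links: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise CorpusError(f"record {self.source_id!r} has an empty name")
        object.__setattr__(
            self,
            "synonyms",
            tuple(s for s in dict.fromkeys(self.synonyms) if s != self.name),
        )


@dataclass(frozen=True)
class EntityPage:
    """A linkable entity: the unit the linker binds text spans to."""

    uid: int
    title: str
    category: str
    body: str = ""


def _normalize_title(title: str) -> str:
    """Merge key for titles: NFC + trim; case folded only for long titles."""
    t = unicodedata.normalize("NFC", title).strip()
    if len(t) <= CASE_SENSITIVE_MAX_LEN:
        return t
    return t.casefold()


def normalize_surface(surface: str) -> str:
    """Lookup key for a surface string (same case policy as titles)."""
    s = unicodedata.normalize("NFC", " ".join(surface.split()))
    if len(s) <= CASE_SENSITIVE_MAX_LEN:
        return s
    return s.casefold()


@dataclass
class LinkingCorpus:
    """Pages + redirects + pagelinks searched by the entity linker."""

    pages: dict[int, EntityPage] = field(default_factory=dict)
    redirects: dict[str, int] = field(default_factory=dict)
    pagelinks: set[tuple[int, int]] = field(default_factory=set)

    # -- lookups ---------------------------------------------------------

    def title_index(self) -> dict[str, int]:
        return {_normalize_title(p.title): p.uid for p in self.pages.values()}

    def surface_candidates(self, surface: str) -> Counter:
        """All uids a surface could denote (titles and redirects).

        The multiset feeds the linker's commonness score: a surface that
        is both one page's title and another page's synonym is ambiguous
        even though the redirect table itself is single-valued.
        """
        key = normalize_surface(surface)
        cands: Counter = Counter()
        for p in self.pages.values():
            if normalize_surface(p.title) == key:
                cands[p.uid] += 1
        for surf, uid in self.redirects.items():
            if normalize_surface(surf) == key:
                cands[uid] += 1
        return cands

    def neighbours(self, uid: int) -> set[int]:
        out = set()
        for a, b in self.pagelinks:
            if a == uid:
                out.add(b)
            elif b == uid:
                out.add(a)
        return out

    def validate(self) -> None:
        for surf, uid in self.redirects.items():
            if uid not in self.pages:
                raise CorpusError(f"redirect {surf!r} -> {uid} has no page")
        for a, b in self.pagelinks:
            if a not in self.pages or b not in self.pages:
                raise CorpusError(f"pagelink ({a},{b}) endpoint has no page")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkingCorpus):
            return NotImplemented
        return (
            self.pages == other.pages
            and self.redirects == other.redirects
            and self.pagelinks == other.pagelinks
        )


# ---------------------------------------------------------------------------
# parsing


_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')

_DELIM_HEADER = ("id", "name", "synonyms", "category", "links")


def _looks_like_delimited(first_line: str) -> bool:
    head = [c.strip().lower() for c in re.split(r"[\t,]", first_line)]
    return head[:2] == ["id", "name"] and set(head) <= set(_DELIM_HEADER)


def parse_obo(stream: IO[str] | str | Path) -> list[OntologyRecord]:
    """Parse an OBO flat file (or the delimited dialect) into records.

    Non-obsolete terms only; obsolete terms are counted and logged.
    The delimited dialect (header ``id,name,synonyms,category,links``
    with ``|``-separated multi-valued fields) is auto-detected from the
    first line.
    """
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text(encoding="utf-8")
    else:
        text = stream.read()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if _looks_like_delimited(first):
        return _parse_delimited(text)
    return _parse_obo_text(text)


def _parse_obo_text(text: str) -> list[OntologyRecord]:
    import io

    n_obsolete = len(re.findall(r"^is_obsolete:\s*true", text, re.M))
    try:
        graph = obonet.read_obo(io.StringIO(text))
    except Exception as exc:  # surface the offending line when we can
        line_no = _first_bad_line(text)
        raise CorpusError(f"malformed OBO stanza near line {line_no}: {exc}") from exc
    namespace = graph.graph.get("ontology", "") or ""
    records = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        if not name:
            continue
        synonyms = tuple(
            m.group(1) for s in data.get("synonym", ()) if (m := _SYNONYM_RE.search(s))
        )
        links: list[str] = list(data.get("is_a", ()))
        for rel in data.get("relationship", ()):
            # "part_of GO:0005575" -> target id
            parts = rel.split()
            if len(parts) == 2:
                links.append(parts[1])
        records.append(
            OntologyRecord(
                source_id=term_id,
                name=name,
                synonyms=synonyms,
                category=data.get("namespace", namespace),
                description=_obo_def(data.get("def", "")),
                links=tuple(links),
            )
        )
    if n_obsolete:
        logger.info("skipped %d obsolete terms", n_obsolete)
    records.sort(key=lambda r: r.source_id)
    return records


def _obo_def(raw: str) -> str:
    m = _SYNONYM_RE.search(raw)
    return m.group(1) if m else raw


def _first_bad_line(text: str) -> int:
    """Best-effort line number of the first structurally broken stanza line."""
    for i, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("!"):
            continue
        if s.startswith("[") and not s.endswith("]"):
            return i
        if not s.startswith("[") and ":" not in s:
            return i
    return 1


def _parse_delimited(text: str) -> list[OntologyRecord]:
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    records = []
    for i, row in enumerate(reader, start=2):
        if row.get("id") is None or row.get("name") is None:
            raise CorpusError(f"malformed delimited row at line {i}")
        records.append(
            OntologyRecord(
                source_id=row["id"].strip(),
                name=row["name"].strip(),
                synonyms=tuple(
                    s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()
                ),
                category=(row.get("category") or "").strip(),
                links=tuple(
                    s.strip() for s in (row.get("links") or "").split("|") if s.strip()
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# corpus construction


def build_corpus(
    records: Sequence[OntologyRecord],
    category_override: str | None = None,
    uid_start: int = 1,
) -> LinkingCorpus:
    """Convert one source's records into a linking corpus.

    uids are dense integers assigned in deterministic order (records
    sorted by source_id) so rebuilds are reproducible.  Dangling links
    are dropped with a log line; duplicate names within the source get
    the later record's title suffixed with its source_id.
    """
    ordered = sorted(records, key=lambda r: r.source_id)
    corpus = LinkingCorpus()
    uid_of: dict[str, int] = {}
    seen_titles: set[str] = set()
    uid = uid_start
    for rec in ordered:
        title = rec.name
        if _normalize_title(title) in seen_titles:
            title = f"{title} ({rec.source_id})"
            logger.warning(
                "duplicate name %r; renamed to %r", rec.name, title
            )
        seen_titles.add(_normalize_title(title))
        category = category_override or rec.category
        corpus.pages[uid] = EntityPage(uid, title, category, rec.description)
        uid_of[rec.source_id] = uid
        uid += 1
    for rec in ordered:
        me = uid_of[rec.source_id]
        for syn in rec.synonyms:
            if syn in corpus.redirects and corpus.redirects[syn] != me:
                logger.warning(
                    "synonym collision: %r already redirects to %d; "
                    "keeping the earlier entry",
                    syn,
                    corpus.redirects[syn],
                )
                continue
            corpus.redirects[syn] = me
        for target in rec.links:
            if target not in uid_of:
                logger.info("dropping dangling link %s -> %s", rec.source_id, target)
                continue
            corpus.pagelinks.add((me, uid_of[target]))
    corpus.validate()
    return corpus


def merge_sources(corpora: Sequence[LinkingCorpus]) -> LinkingCorpus:
    """Union several corpora into one, resolving title/surface collisions.

    Pages with the same normalized title are merged into one uid
    (categories and bodies concatenated); redirects are re-pointed; a
    surface that collides with a title loses to the title, and among
    colliding redirects the earlier source wins.  uids are reassigned
    densely so the merge result is deterministic.
    """
    merged = LinkingCorpus()
    by_title: dict[str, int] = {}
    uid_map: list[dict[int, int]] = []
    next_uid = 1
    for corpus in corpora:
        mapping: dict[int, int] = {}
        for uid in sorted(corpus.pages):
            page = corpus.pages[uid]
            key = _normalize_title(page.title)
            if key in by_title:
                target = by_title[key]
                old = merged.pages[target]
                cats = old.category
                if page.category and page.category not in cats.split("; "):
                    cats = f"{cats}; {page.category}" if cats else page.category
                body = old.body
                if page.body and page.body not in body:
                    body = f"{body}\n{page.body}" if body else page.body
                merged.pages[target] = EntityPage(target, old.title, cats, body)
                mapping[uid] = target
            else:
                merged.pages[next_uid] = EntityPage(
                    next_uid, page.title, page.category, page.body
                )
                by_title[key] = next_uid
                mapping[uid] = next_uid
                next_uid += 1
        uid_map.append(mapping)
    # redirects: title beats redirect; earlier source beats later
    title_keys = {_normalize_title(p.title) for p in merged.pages.values()}
    for corpus, mapping in zip(corpora, uid_map):
        for surf, uid in sorted(corpus.redirects.items()):
            target = mapping[uid]
            if _normalize_title(surf) in title_keys:
                if normalize_surface(surf) != normalize_surface(
                    merged.pages[target].title
                ):
                    logger.info(
                        "redirect %r collides with a page title; dropped", surf
                    )
                continue
            if surf in merged.redirects and merged.redirects[surf] != target:
                logger.info(
                    "redirect %r collides across sources; earlier source wins", surf
                )
                continue
            merged.redirects[surf] = target
    for corpus, mapping in zip(corpora, uid_map):
        for a, b in corpus.pagelinks:
            ma, mb = mapping[a], mapping[b]
            if ma != mb:
                merged.pagelinks.add((ma, mb))
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# export / import

_TABLES = ("pages", "category", "pageslink", "redirects")


def export_tables(corpus: LinkingCorpus, directory: str | Path) -> None:
    """Write pages/category/pageslink/redirects CSVs (UTF-8, headered)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        with open(directory / "pages.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["uid", "title", "body"])
            for uid in sorted(corpus.pages):
                p = corpus.pages[uid]
                w.writerow([uid, p.title, p.body])
        with open(directory / "category.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["uid", "category"])
            for uid in sorted(corpus.pages):
                w.writerow([uid, corpus.pages[uid].category])
        with open(directory / "pageslink.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["uid_from", "uid_to"])
            for a, b in sorted(corpus.pagelinks):
                w.writerow([a, b])
        with open(directory / "redirects.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["surface", "uid"])
            for surf in sorted(corpus.redirects):
                w.writerow([surf, corpus.redirects[surf]])
    except OSError as exc:
        raise CorpusError(f"failed writing corpus table: {exc.filename}") from exc


def import_tables(directory: str | Path) -> LinkingCorpus:
    """Read the four CSV tables back into a LinkingCorpus."""
    directory = Path(directory)
    corpus = LinkingCorpus()
    categories: dict[int, str] = {}
    with open(directory / "category.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            categories[int(row["uid"])] = row["category"]
    with open(directory / "pages.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            uid = int(row["uid"])
            corpus.pages[uid] = EntityPage(
                uid, row["title"], categories.get(uid, ""), row["body"]
            )
    with open(directory / "pageslink.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            corpus.pagelinks.add((int(row["uid_from"]), int(row["uid_to"])))
    with open(directory / "redirects.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            corpus.redirects[row["surface"]] = int(row["uid"])
    corpus.validate()
    return corpus
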