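# Methods

This note records the models, parameters and design decisions behind
litnet, in the order the pipeline applies them.

## Linking corpus

Ontology and database sources are normalised into four relational
tables (pages, category, pageslink, redirects).  Design choices:

- **uid assignment.** Dense integers in deterministic order (records
  sorted by source id; sources processed in configuration order), so a
  rebuild from the same inputs yields byte-identical tables.
- **Title normalisation for merging.** Unicode NFC + whitespace trim.
  Case is folded only for titles longer than 5 characters: short gene
  symbols are case-significant (BSG ≠ bsg), long descriptive names are
  not.  The same rule governs surface matching in the linker.
- **Collision policy.** When a synonym surface collides with a page
  title, the title wins (the redirect is dropped and logged).  When two
  sources redirect the same surface to different entities, the earlier
  source wins.  Pages with identical normalised titles merge into one
  uid with concatenated categories and bodies.
- **Link types.** Only `is_a` and explicit `relationship:` targets are
  read from OBO; cross-ontology xrefs are ignored.  OBO parsing is
  delegated to `obonet`; obsolete terms are excluded and counted.
  A simple delimited dialect (`id,name,synonyms,category,links`, with
  `|`-separated multi-fields) covers non-ontology databases whose
  relation semantics do not map onto OBO.

## Entity linking and ρ

The linker matches maximal token n-grams (n ≤ 6) against titles and
redirects, longest match first, ties to the leftmost, never producing
overlapping spans.  Each annotation is scored

ρ = (commonness + coherence) / 2,

- commonness = (surface entries mapping this surface to the chosen
  uid) / (surface entries mapping it to any uid).  Ambiguity arises
  when a surface is simultaneously one page's title and another's
  synonym; the binding itself follows the title-beats-redirect policy,
  but the competing candidate still discounts commonness.
- coherence = mean over the other entities annotated in the document of
  a relatedness score: 1 if a pagelink joins the two entities (either
  direction), else the Jaccard overlap of their pagelink
  neighbourhoods.  A document with a single annotation has no context,
  so ρ reduces to commonness.

This scorer is deliberately kept behind a single seam
(`linker.score_rho`) so an alternative (e.g. an embedding-based
relatedness) can be injected without touching the pipeline.  The
default acceptance threshold is ρ > 0.3, configurable; filtering is
strict (`>`), so threshold 1 rejects everything.

Acronym handling is document-local: a parenthesised 2–10 character
uppercase/digit token directly following an annotated long form is
accepted as that entity's acronym when the long form's word initials
appear in order within the acronym and the first letters agree
(PLGF ↔ *p*lacental *g*rowth *f*actor passes; XYZ does not).  Later
occurrences of the acronym are re-bound to the long form's entity and
inherit the larger of the two ρ values.  Mentions before the definition
are untouched; the override changes only uids, never spans, and is
idempotent.

## Syntactic analysis

Tokens carry Penn-Treebank POS tags and ClearNLP-style dependency
labels, with `X` as a catch-all for punctuation-like tokens.  Parsing
is a seam: any object returning sentences of contract-valid tokens can
drive the pipeline.  Three analyzers ship with the package:

- a **fixture analyzer** replaying hand-written parses from a JSON
  format (`{"sentences": [{char_start, char_end, tokens: [...]}]}`,
  bit-exact on round trip) — the deterministic path used by all tests;
- a **segmenter** (abbreviation- and decimal-aware sentence splitting,
  flat trees) for segmentation-only uses;
- a **heuristic analyzer**: lexicon-driven POS assignment plus pattern
  attachment for simple declarative clauses (pre-verbal subject,
  passive `be + VBN (+ by-agent)`, post-verbal objects, conjunction
  chains, prepositional and parenthetical attachment).  It is adequate
  for abstract-style SVO prose and for the fixture templates, and is
  the default when no parses are supplied; users with complex text
  should inject a pretrained statistical parser through the seam.  No
  parser is trained in this package.

Tree queries used downstream:

- `verb_between(i, j)` returns the lowest common ancestor of the two
  tokens when it is a verb; otherwise the verb on the undirected head
  path nearest the LCA (ties to the smaller index, keeping the function
  symmetric); otherwise none.  When the LCA is a conjoined verb the
  conjunct itself is returned, not the clause root.  Nominal relation
  words from the verb dictionary (currently "ubiquitination") are
  admitted in root/`acl` position as verb substitutes.
- `is_passive(v)` is purely structural: true iff the verb has an
  `auxpass` or `nsubjpass` dependent; word forms are never consulted.

## Relation extraction

Token pruning removes POS tags
{DT, IN, CC, TO, UH, SYM, HYPH, LS, NFP, ADD, AFX}, URL/email-shaped
tokens, and a configurable stop-word list (verbs are never dropped as
stop-words).

For every unordered pair of distinct entities in a sentence, a triple
is emitted iff `verb_between` finds a governing verb that survives
pruning and **both** spot heads reach the verb through dependency
labels in the admissible set
{nsubj, nsubjpass, dobj, pobj, prep, conj, appos, compound, attr,
agent, dative} (configurable).  The verb's own attachment label is not
part of either path.  Synonym spots of one entity (long form +
acronym) collapse into a single triple keeping the larger ρ per
endpoint.

Orientation: with an active verb the `nsubj` entity is the source and
the object-path entity the target; with a passive verb the roles swap
(the `nsubjpass` entity becomes the target, the agent the source);
when neither entity sits on a subject path the edge is undirected with
endpoints in sentence order.  A `neg` dependent sets a `negated` flag
on the triple but neither flips nor drops the edge.

Adjacent sentences (S_i, S_{i+1}) are linked only in the unambiguous
case: S_{i+1}'s root verb has a bare personal-pronoun subject and S_i
contains exactly one annotated entity, which substitutes for the
pronoun.  Intra-sentential pronouns are ignored.

## Edge weights

- `tf(e,p) = f_{e,p} / Σ_{e'∈p} f_{e',p}`; a document with no edges has
  undefined tf, reported as 0 with a warning.
- `idf(e,P) = ln(N / df(e))`, natural log; querying an unobserved edge
  is a domain error.  The corpus-level weight of an edge is the sum of
  its per-document tf·idf values, preserving additivity across
  documents.
- `mrho = (ρ_a · ρ_b) / 2`, implemented verbatim; its range is
  [0, 0.5].  At the graph level the maximum ρ-product across an edge's
  occurrences is used.
- `bio`: 0 when the lemmatized verb is a dictionary member; otherwise
  1 − max cosine similarity between boundary-padded character-trigram
  count vectors of the lemma and each dictionary entry.  0 therefore
  means "biological" — dictionary membership short-circuits before any
  vector comparison.  Trigram vectors were chosen because they are
  deterministic, dependency-free and adequate for a 28-entry
  dictionary; the vectorizer is a seam for word embeddings.  Strict
  filtering keeps triples with bio < 0.5 (cutoff configurable).
- The dictionary ships as a plain text file (one form per line) and is
  lemmatized at load; mixed inflections ("Associates", "Upregulates")
  normalise to their lemmas, and "Ubiquitination" is retained as the
  single nominal predicate.

A directed and an undirected edge over the same pair and verb are kept
distinct by default (`merge_directions=True` collapses them).
Gold-standard evaluation counts a positive pair as tp when any edge
connects it — by default ignoring direction, reported in the result —
and derives accuracy, sensitivity, specificity and PPV, with 0/0 rates
returned as None rather than raised.

## Synthetic data

The fixture generator emulates abstract-like documents in which known
entities interact through explicit verbs.  Defaults (chosen once as the
study conditions): 6 entities in each of 3 categories (Genes, Diseases,
Drugs), 1 lowercase synonym per entity, 20 documents × 4 sentences,
planted-triple density 0.9, distractor-verb rate 0, ambiguous-surface
rate 0.  Sentences are drawn from templates covering every admissible
dependency label — active/passive clauses, noun compounds, conjoined
objects, parenthetical appositions with synonyms, prepositional
objects, attributes, datives, an undirected both-objects pattern, and
the pronoun-bridged two-sentence pattern — each with exact gold
character offsets, gold oriented triples and a matching hand-template
parse.  Distractor sentences use verbs far from the biological
dictionary (resemble, concern, precede, accompany).  All randomness
flows from one `random.Random(seed)`.

What the fixtures do **not** emulate: parser errors, nested or
embedded clauses, discontinuous mentions, typographical noise, and the
surface diversity of real prose.  Passing the no-noise benchmark
therefore shows the extraction logic is faithful to its rules, not
that recall on real literature is 100%; on real text the binding
constraint is parse quality through the analyzer seam.

## Problem sizes and numerics

Tests and the acceptance script run on the packaged one-sentence
worked example, 20-document synthetic sets, and hand-built graphs —
sizes chosen so the whole suite completes in seconds while still
exercising every rule (each template appears many times across 20×4
sentences).  The pipeline is fully deterministic given fixed inputs:
no step samples, and all collections are iterated in sorted or
insertion order.  Floating-point comparisons in tests use standard
relative tolerances; the weighting identities (tf summing to 1, idf of
a ubiquitous edge = 0, mrho(1,1) = 0.5) hold exactly in IEEE doubles
for the fixture counts used.

## Known limitations

- The ρ scorer is a commonness/coherence stand-in with the documented
  contract (range, context sensitivity), not a re-implementation of any
  particular production linker; rankings may differ from such systems.
- The heuristic analyzer mis-attaches in clauses with embedded
  complements; it is a convenience default, not a parser.
- Acronym handling covers only the parenthetical definition pattern.
- Adjacent-sentence linking requires a single unambiguous antecedent;
  genuine coreference resolution is out of scope.
- Relationships from non-ontology databases map through the delimited
  table's `links` column; richer relation semantics (e.g. typed
  drug–target pairs) are flattened to untyped pagelinks.
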