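# litnet

**litnet** infers a weighted, partially directed biomedical knowledge
graph from a set of documents.  It is aimed at researchers who want a
quick, reproducible map of the entities (genes, diseases, drugs,
ontology terms) mentioned in a body of literature and of the verb-
mediated relations connecting them — e.g. to supplement curated pathway
databases with interactions that are described in papers but missing
from the databases.

## How it works

1. **Gazetteer construction.** Ontologies (OBO files) and database term
   tables are converted into an encyclopedia-style linking corpus:
   *pages* (one per entity, with a system-generated uid, title,
   category, body), *redirects* (one per synonym, e.g. CD147 → BSG) and
   *pagelinks* (term-to-term relations such as `is_a`).  Multiple
   sources merge into one corpus under a deterministic collision policy.
2. **Entity linking.** Maximal token n-grams matching a page title or
   redirect become annotations, scored with

   ρ = (commonness + coherence) / 2 ∈ [0, 1],

   where commonness is the fraction of surface entries pointing at the
   chosen entity and coherence is the mean pagelink relatedness to the
   other entities in the document.  Annotations below a user threshold
   (default 0.3) are discarded.  Parenthetically defined acronyms
   ("placental growth factor (PLGF)") re-bind later occurrences of the
   acronym document-wide, disambiguating acronyms that collide with
   gene symbols.
3. **Relation extraction.** Sentences are POS/dependency annotated
   through a pluggable analyzer seam (hand-written parse fixtures, a
   built-in rule-based analyzer, or any injected pretrained parser).
   For each pair of co-sentential entities the verb governing both
   spots — the dependency root between the two noun parts — yields a
   candidate triple ⟨subject, verb, object⟩, subject to a coherence
   check on the dependency labels along both paths.  Direction follows
   voice (passives are swapped via `nsubjpass`/`agent`); a restricted
   pronoun rule bridges adjacent sentences.
4. **Weighting.** Each edge e in document set P carries
   - `tf.idf(e,p,P) = tf(e,p) · idf(e,P)` with `tf(e,p) = f_{e,p} / Σ_{e'∈p} f_{e',p}`
     and `idf(e,P) = ln(N / |{p ∈ P : e ∈ p}|)` — counting *edges*, not words;
   - `mrho(e) = (ρ_a · ρ_b) / 2`, from the endpoint annotation confidences;
   - `bio(e)`: 0 when the verb lemma is in the packaged dictionary of 28
     biological verb forms, otherwise 1 − max character-trigram cosine
     to the dictionary (0 = biological, 1 = unrelated).
5. **Assembly & evaluation.** Triples aggregate into a graph (GraphML /
   Cytoscape JSON / CSV exports) that can be scored against gold
   positive and negative pair lists (accuracy, sensitivity, specificity,
   PPV).

## Worked example

```bash
python examples/worked_example.py
```

```
sentence: CD147 regulates several VEGF isoforms and placental growth factor (PLGF), and it has unique effects on trophoblastic function.

annotations (surface -> entity, rho):
  'CD147'                        -> BSG  rho=1.00
  'VEGF'                         -> VEGFA  rho=1.00
  'placental growth factor'      -> PGF  rho=1.00
  'PLGF'                         -> PGF  rho=1.00

edges (source --verb--> target, weights):
  BSG --regulate--> VEGFA   tfidf=0.000 mrho=0.500 bio=0.000
  BSG --regulate--> PGF   tfidf=0.000 mrho=0.500 bio=0.000
```

Four text spans collapse onto three entities (PLGF and its long form
are the same gene) and exactly two directed edges leave BSG, because
CD147 is the grammatical subject of "regulates" and both VEGF and PLGF
are reached through admissible object paths (`dobj`, `conj`, `appos`).
The second clause ("it has unique effects…") contributes no edge: its
nouns are not gazetteer entities.  `tfidf` is 0 with a single document,
`mrho` is at its 0.5 maximum (both ρ = 1), and `bio` is 0 because
"regulate" is a dictionary verb.

The other scripts in `examples/` show corpus construction from OBO,
a synthetic precision/recall benchmark, and gold-standard evaluation.

## Command line

```bash
litnet build-corpus ontology.obo terms.csv --out corpus/
litnet run --input docs/ --corpus corpus/ --rho-threshold 0.3 \
           --strict-bio --format graphml --out network.graphml
```

`litnet run` accepts a directory of `.txt` files or a JSON manifest,
optional pre-computed parse fixtures (`--parses`), and writes the
papers/annotations/edge tables or a single graph file.

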