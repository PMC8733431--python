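"""Build a linking corpus from an ontology snippet and search it.

Parses a small OBO document, converts it into the pages/redirects/
pagelinks tables the entity linker consumes, and detects spots in a
sentence.
"""

import io

from litnet.corpus import build_corpus, parse_obo
from litnet.linker import detect_spots, score_all

OBO = """format-version: 1.2
ontology: demo

[Term]
id: DEMO:001
name: pterygium
synonym: "surfer's eye" EXACT []
is_a: DEMO:002

[Term]
id: DEMO:002
name: corneal disease
"""

records = parse_obo(io.StringIO(OBO))
corpus = build_corpus(records, category_override="Diseases")
print(f"{len(corpus.pages)} pages, {len(corpus.redirects)} redirects, "
      f"{len(corpus.pagelinks)} pagelinks")

text = "Surfer's eye is a mild form of corneal disease."
annotations = score_all(detect_spots("demo-doc", text, corpus), corpus)
for a in annotations:
    print(f"  [{a.start}:{a.end}] {a.surface!r} -> "
          f"{corpus.pages[a.uid].title} (rho={a.rho:.2f})")

# Both the synonym surface ("surfer's eye", matched case-insensitively
# because it is longer than a gene symbol) and the term name resolve to
# corpus entities; rho is high because the two terms are joined by an
# is_a pagelink, so they corroborate each other.
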