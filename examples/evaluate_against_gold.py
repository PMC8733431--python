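"""Score an inferred network against known positive/negative pairs.

Builds a small graph by hand, evaluates it against four known
interactions and four known non-interactions, and prints the confusion
counts and derived rates — the same calculator one would point at
pathway-database positives and a negative interaction set.
"""

from litnet.graph import GraphEdge, GraphNode, KnowledgeGraph, evaluate_against_gold

graph = KnowledgeGraph()
for a, b in [(1, 2), (1, 3), (1, 4), (2, 3)]:
    for u in (a, b):
        graph.nodes[u] = GraphNode(u, f"GENE{u}", "Genes")
    graph.edges.append(
        GraphEdge(a, b, "regulate", directed=True, provenance=[("doc", 0)])
    )

result = evaluate_against_gold(
    graph,
    positives=[(1, 2), (1, 3), (1, 4), (1, 5)],  # known interactions
    negatives=[(2, 3), (2, 4), (2, 5), (3, 4)],  # known non-interactions
    ignore_direction=True,
)

print(f"tp={result.tp} fn={result.fn} fp={result.fp} tn={result.tn}")
print(f"accuracy    = {result.accuracy:.2f}")
print(f"sensitivity = {result.sensitivity:.2f}")
print(f"specificity = {result.specificity:.2f}")
print(f"ppv         = {result.ppv:.2f}")

# The graph contains 3 of the 4 known interactions (one missed -> fn=1)
# and 1 of the 4 known non-interactions (a spurious edge -> fp=1), so
# every rate lands at 0.75.
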