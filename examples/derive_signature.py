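"""Derive a cluster gene signature from a differential-expression marker table.

Plants the published 11-gene C0 signature among 25 decoy rows that fail the
fold-change > 1.5 / adjusted-P < 0.001 filter, then recovers it by
filtering against an adaptive-immunity gene universe.
"""

import tcellstrat as ts

published = ts.bundled_signatures()["C0"]
planted = [("C0", gene, 2.0 + 0.1 * i, 1e-5) for i, gene in enumerate(published.genes)]
markers = ts.generate_marker_table(planted, decoys=25, seed=3)

universe = ts.GeneSet(
    name="adaptive_immunity_toy",
    genes=frozenset(set(published.genes) | {"CD28", "PDCD1", "TIGIT"}),
)
derived = ts.derive_signature(markers, "C0", universe)

print(f"marker table rows: {len(markers)}")
print(f"derived signature ({len(derived)} genes): {' '.join(derived.genes)}")
print(f"matches published C0 gene set: {set(derived.genes) == set(published.genes)}")

# The derived set equals the planted genes exactly: every decoy fails at
# least one of the three predicates (fold change, adjusted P, universe).
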