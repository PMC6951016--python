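"""Featurize molecules into graphs and inspect the directed-edge structure.

Parses a few SMILES into heavy-atom graphs with one-hot atom/bond features
and builds the directed-edge view that powers the edge-memory architecture:
for each directed edge (v, w), the incoming edges at v exclude the reverse
edge (w, v), so information never flows straight back.
"""

import molmpnn as mm

for smiles in ("CCO", "c1ccccc1", "CC(=O)O"):
    g = mm.featurize_molecule(smiles)
    print(f"{smiles}: {g.n_atoms} atoms, {g.n_directed_edges} directed edges, "
          f"node feature width {g.node_features.shape[1]}")

# Directed-edge view on ethanol C(0)-C(1)-O(2)
g = mm.featurize_molecule("CCO")
view = mm.build_directed_edge_view(g)
for i, (v, w) in enumerate(g.edge_index):
    incoming = [(int(a), int(b)) for a, b in
                (g.edge_index[j] for j in view.incoming_lists[i])]
    print(f"edge ({v}->{w}): incoming from {incoming or 'nothing'}")
# The edge 1->2 (C->O) receives only from 0->1, never from its own
# reverse 2->1 — that is the no-backflow property.
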