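"""SMILES -> featurized molecular graphs.

A molecule is represented as an undirected heavy-atom graph stored with both
directed copies of every bond, so the same container serves the node-centred
architectures (which sum over neighbours) and the edge-memory architecture
(which keeps a hidden state per directed edge).

Node features are blocks of one-hot / integer codes over atom type, degree,
implicit valence, formal charge, radical electrons, hybridization,
aromaticity and total hydrogen count. Edge features are a one-hot over the
four modelled bond classes: single, double, triple, aromatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomFeatureSchema",
    "MolecularGraph",
    "DirectedEdgeView",
    "BatchedGraph",
    "featurize_molecule",
    "build_directed_edge_view",
    "batch_graphs",
    "unbatch_graphs",
    "SmilesParseError",
    "FeaturizationError",
]

BOND_CLASSES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class FeaturizationError(ValueError):
    """Raised when a molecule falls outside the feature schema (e.g. bond class)."""


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Fixed-width, fixed-order atom feature blocks.

    The element vocabulary covers the common organic elements with a trailing
    "other" slot; hydrogens are implicit. Count-valued blocks (degree,
    implicit valence, H count) are one-hot with the top bucket absorbing
    overflow, so the total width is constant across datasets.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I",
                                 "P", "B", "Si", "Se")
    max_degree: int = 6
    max_valence: int = 6
    max_h: int = 4

    @property
    def width(self) -> int:
        return (len(self.elements) + 1            # atom type (+ other)
                + self.max_degree + 1             # degree 0..max
                + self.max_valence + 1            # implicit valence 0..max
                + 1                               # formal charge (integer)
                + 1                               # radical electrons (integer)
                + len(_HYBRIDIZATIONS)            # hybridization one-hot
                + 1                               # aromaticity flag
                + self.max_h + 1)                 # total H count 0..max

    def atom_vector(self, atom: Chem.Atom) -> np.ndarray:
        v = np.zeros(self.width)
        pos = 0

        symbol = atom.GetSymbol()
        idx = self.elements.index(symbol) if symbol in self.elements else len(self.elements)
        v[pos + idx] = 1.0
        pos += len(self.elements) + 1

        v[pos + min(atom.GetDegree(), self.max_degree)] = 1.0
        pos += self.max_degree + 1

        v[pos + min(atom.GetImplicitValence(), self.max_valence)] = 1.0
        pos += self.max_valence + 1

        v[pos] = float(atom.GetFormalCharge())
        pos += 1
        v[pos] = float(atom.GetNumRadicalElectrons())
        pos += 1

        hyb = atom.GetHybridization()
        if hyb in _HYBRIDIZATIONS:
            v[pos + _HYBRIDIZATIONS.index(hyb)] = 1.0
        pos += len(_HYBRIDIZATIONS)

        v[pos] = 1.0 if atom.GetIsAromatic() else 0.0
        pos += 1

        v[pos + min(atom.GetTotalNumHs(), self.max_h)] = 1.0
        return v


@dataclass
class MolecularGraph:
    """One featurized molecule: node features, directed edge list, edge features."""

    node_features: np.ndarray          # [n_atoms, d_node]
    edge_index: np.ndarray             # [n_directed_edges, 2] (tail, head)
    edge_features: np.ndarray          # [n_directed_edges, 4] bond-class one-hot
    n_atoms: int
    smiles: str = ""

    @property
    def n_directed_edges(self) -> int:
        return self.edge_index.shape[0]

    def neighbours(self, v: int) -> list[int]:
        return [int(w) for t, w in self.edge_index if t == v]


@dataclass
class DirectedEdgeView:
    """Index structure for directed-edge message passing.

    For directed edge i = (v, w): ``tails[i] = v``, ``heads[i] = w``,
    ``reverse_index[i]`` is the position of (w, v), and
    ``incoming_lists[i]`` holds the positions of edges (k, v) with k != w —
    the incoming edges at the tail, excluding the reverse edge, so
    information never flows straight back where it came from.
    """

    tails: np.ndarray
    heads: np.ndarray
    reverse_index: np.ndarray
    incoming_lists: list[np.ndarray] = field(default_factory=list)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def featurize_molecule(smiles: str,
                       schema: AtomFeatureSchema | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens stay implicit (heavy-atom graph). Every bond is stored as two
    directed edges at consecutive positions (2i, 2i+1) with identical
    bond-class one-hots; a bond outside {single, double, triple, aromatic}
    raises :class:`FeaturizationError`.
    """
    schema = schema or AtomFeatureSchema()
    mol = _parse(smiles)
    n = mol.GetNumAtoms()
    node_features = np.array([schema.atom_vector(a) for a in mol.GetAtoms()]) \
        if n else np.zeros((0, schema.width))

    pairs, feats = [], []
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt not in BOND_CLASSES:
            raise FeaturizationError(
                f"bond type {bt} outside the 4 modelled classes in {smiles!r}")
        onehot = np.zeros(len(BOND_CLASSES))
        onehot[BOND_CLASSES.index(bt)] = 1.0
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        pairs.extend([(v, w), (w, v)])
        feats.extend([onehot, onehot.copy()])

    edge_index = np.array(pairs, dtype=np.intp).reshape(-1, 2)
    edge_features = (np.array(feats) if feats
                     else np.zeros((0, len(BOND_CLASSES))))
    return MolecularGraph(node_features, edge_index, edge_features, n, smiles)


def build_directed_edge_view(graph: MolecularGraph) -> DirectedEdgeView:
    """Build reverse-edge pairing and no-backflow incoming lists."""
    tails = graph.edge_index[:, 0].copy()
    heads = graph.edge_index[:, 1].copy()
    n_edges = len(tails)
    # Bond i occupies slots 2i and 2i+1, so the reverse is the slot-mate.
    reverse_index = np.arange(n_edges, dtype=np.intp) ^ 1

    by_head: dict[int, list[int]] = {}
    for j in range(n_edges):
        by_head.setdefault(int(heads[j]), []).append(j)

    incoming = []
    for i in range(n_edges):
        rev = int(reverse_index[i])
        inc = [j for j in by_head.get(int(tails[i]), []) if j != rev]
        incoming.append(np.array(inc, dtype=np.intp))
    return DirectedEdgeView(tails, heads, reverse_index, incoming)


@dataclass
class BatchedGraph:
    """Disjoint union of molecular graphs with a molecule-membership index."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    node_membership: np.ndarray        # node -> molecule index
    n_molecules: int
    n_atoms_per_graph: np.ndarray
    smiles: list[str]

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return self.edge_index.shape[0]


def batch_graphs(graphs: list[MolecularGraph]) -> BatchedGraph:
    """Disjoint union with node indices offset per molecule."""
    if not graphs:
        raise ValueError("batch_graphs requires a non-empty list")
    node_offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
    node_features = np.concatenate([g.node_features for g in graphs], axis=0) \
        if node_offsets[-1] else np.zeros((0, graphs[0].node_features.shape[1]))
    edge_index = np.concatenate(
        [g.edge_index + off for g, off in zip(graphs, node_offsets[:-1])], axis=0)
    edge_features = np.concatenate([g.edge_features for g in graphs], axis=0)
    membership = np.concatenate(
        [np.full(g.n_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)])
    return BatchedGraph(node_features, edge_index, edge_features, membership,
                        len(graphs), np.diff(node_offsets),
                        [g.smiles for g in graphs])


def unbatch_graphs(batch: BatchedGraph) -> list[MolecularGraph]:
    """Invert :func:`batch_graphs` exactly."""
    graphs = []
    node_offsets = np.cumsum([0, *batch.n_atoms_per_graph])
    for i in range(batch.n_molecules):
        lo, hi = node_offsets[i], node_offsets[i + 1]
        emask = (batch.edge_index[:, 0] >= lo) & (batch.edge_index[:, 0] < hi)
        graphs.append(MolecularGraph(
            batch.node_features[lo:hi].copy(),
            batch.edge_index[emask] - lo,
            batch.edge_features[emask].copy(),
            int(hi - lo),
            batch.smiles[i]))
    return graphs
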