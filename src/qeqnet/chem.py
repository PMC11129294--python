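"""Molecular graphs for charge assignment.

A molecule is abstracted as a graph: atoms are nodes, bonds are (undirected)
edges. Node features are *resonance-independent* local descriptors — element
identity, connectivity degree, symmetrized formal charge, ring membership and
aromaticity — computed without any reference to 3D geometry, kekulé structure
or conformer choice, so that any depiction of the same molecule featurizes
identically. Graphs can be batched by concatenating their adjacency structure
block-diagonally, which lets a whole library of molecules flow through the
network in one pass while keeping molecules informationally isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    BatchError,
    DimensionError,
    DisconnectedMoleculeError,
    MoleculeValidationError,
    UnsupportedElementError,
)

#: Default element vocabulary; one-hot encoded, so unseen elements are rejected.
DEFAULT_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Featurization scheme version; checkpoints record it and loaders enforce it.
FEATURE_VERSION = "qeqnet-feat-v1"


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, integer formal charge, aromatic flag.

    The aromatic flag is perceived at parse time (it needs bond orders, which
    the connectivity-only graph does not carry); molecules constructed
    programmatically default to non-aromatic.
    """

    element: str
    formal_charge: int = 0
    aromatic: bool = False


@dataclass
class Molecule:
    """Connectivity-only molecule with explicit hydrogens.

    ``bonds`` are unordered pairs of 0-based atom indices. Bond orders are
    deliberately absent: every downstream computation is resonance-independent.
    The optional ``rdmol`` is a cached RDKit molecule kept by the parsers so
    writers can reproduce bond orders; it never influences charges.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    name: str = ""
    rdmol: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int]] = []
        for (i, j) in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise MoleculeValidationError(
                    f"molecule {self.name!r}: bond ({i},{j}) has invalid atom indices"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MoleculeValidationError(
                    f"molecule {self.name!r}: duplicate bond ({i},{j})"
                )
            seen.add(key)
            norm.append(key)
        self.bonds = norm
        if n > 0 and not _is_connected(n, norm):
            raise DisconnectedMoleculeError(
                f"molecule {self.name!r} has disconnected fragments; the total-charge "
                "constraint is per-molecule, so fragments must be charged separately"
            )

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def neighbor_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def permuted(self, perm: Sequence[int]) -> "Molecule":
        """Relabel atoms: new index ``perm[i]`` gets old atom ``i``."""
        perm = list(perm)
        if sorted(perm) != list(range(self.num_atoms)):
            raise MoleculeValidationError("not a permutation of atom indices")
        atoms = [None] * self.num_atoms
        for old, new in enumerate(perm):
            atoms[new] = self.atoms[old]
        bonds = [(perm[i], perm[j]) for i, j in self.bonds]
        return Molecule(atoms=list(atoms), bonds=bonds, name=self.name)


def _is_connected(n: int, bonds: Iterable[tuple[int, int]]) -> bool:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    stack = [0]
    seen[0] = True
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                count += 1
                stack.append(v)
    return count == n


def total_formal_charge(mol: Molecule) -> int:
    """Total molecular charge Q = sum of atomic formal charges.

    This integer is the right-hand side of the charge-conservation constraint
    that the equilibration step enforces exactly.
    """
    return sum(a.formal_charge for a in mol.atoms)


@dataclass(frozen=True)
class FeaturizationConfig:
    """Featurization scheme: which blocks go into the node feature rows.

    elements        one-hot vocabulary (order defines column order)
    max_degree      degrees 0..max_degree one-hot (clamped above)
    charge_min/max  integer grid for the soft formal-charge encoding
    version         scheme tag; model checkpoints must match it
    """

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    max_degree: int = 6
    charge_min: int = -2
    charge_max: int = 2
    include_ring: bool = True
    include_aromatic: bool = True
    version: str = FEATURE_VERSION

    @property
    def n_features(self) -> int:
        n = len(self.elements) + (self.max_degree + 1)
        n += self.charge_max - self.charge_min + 1
        n += int(self.include_ring) + int(self.include_aromatic)
        return n

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "max_degree": self.max_degree,
            "charge_min": self.charge_min,
            "charge_max": self.charge_max,
            "include_ring": self.include_ring,
            "include_aromatic": self.include_aromatic,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturizationConfig":
        d = dict(d)
        d["elements"] = tuple(d["elements"])
        return cls(**d)

    def with_elements(self, elements: Sequence[str]) -> "FeaturizationConfig":
        return replace(self, elements=tuple(elements))


#: refinement rounds for equivalence classes; resonance equivalence is a local
#: phenomenon, and a bounded round count keeps featurization O(N) on chains.
WL_MAX_ROUNDS = 16


def atom_equivalence_classes(mol: Molecule) -> list[int]:
    """Partition atoms by iterated neighborhood refinement (Weisfeiler-Lehman).

    Colors are seeded by element only — formal charges and bond orders are
    excluded on purpose, so that resonance-equivalent atoms (the two oxygens
    of a carboxylate, say) land in the same class. Refinement runs until the
    partition stabilizes or a bounded round count is hit; the returned ids
    are arbitrary but consistent within a call.
    """
    adj = mol.neighbor_lists()
    colors: list[int] = []
    table: dict[object, int] = {}
    for a in mol.atoms:
        colors.append(table.setdefault(a.element, len(table)))
    for _ in range(max(1, min(mol.num_atoms, WL_MAX_ROUNDS))):
        table = {}
        new = []
        for i in range(mol.num_atoms):
            sig = (colors[i], tuple(sorted(colors[j] for j in adj[i])))
            new.append(table.setdefault(sig, len(table)))
        if new == colors:
            break
        colors = new
    return colors


def ring_membership(mol: Molecule) -> list[bool]:
    """True for atoms on at least one cycle of the bond graph.

    Computed from connectivity alone (edges not on any cycle are bridges).
    """
    n = mol.num_atoms
    if n == 0:
        return []
    if len(mol.bonds) < n:  # connected with < n edges: a tree, no cycles
        return [False] * n
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(mol.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    in_ring = [False] * n
    for i, j in mol.bonds:
        if frozenset((i, j)) not in bridges:
            in_ring[i] = True
            in_ring[j] = True
    return in_ring


def _soft_charge_encoding(value: float, lo: int, hi: int) -> np.ndarray:
    """Linear-interpolation encoding of a (possibly fractional) formal charge.

    Integers give an exact one-hot; a symmetrized half-integer (e.g. -0.5 on
    each carboxylate oxygen) splits its weight between the two adjacent bins,
    keeping the feature width fixed while staying resonance-independent.
    """
    v = min(max(value, lo), hi)
    enc = np.zeros(hi - lo + 1)
    base = int(np.floor(v))
    frac = v - base
    enc[base - lo] = 1.0 - frac
    if frac > 0.0:
        enc[base - lo + 1] = frac
    return enc


def featurize_atoms(mol: Molecule, scheme: FeaturizationConfig | None = None) -> np.ndarray:
    """N x F node feature matrix.

    Row i depends only on atom i's local descriptors. Formal charges are first
    averaged within element/connectivity equivalence classes so that
    resonance-equivalent depictions of the same molecule yield identical rows.
    """
    scheme = scheme or FeaturizationConfig()
    elem_idx = {el: k for k, el in enumerate(scheme.elements)}
    for a in mol.atoms:
        if a.element not in elem_idx:
            raise UnsupportedElementError(
                f"molecule {mol.name!r}: element {a.element!r} is outside the "
                f"one-hot vocabulary {scheme.elements}; one-hot encodings cannot "
                "generalize to unseen elements"
            )
    n = mol.num_atoms
    fcs = [a.formal_charge for a in mol.atoms]
    if len(set(fcs)) == 1:
        # symmetrization cannot change anything; common fast path
        sym_fc: list[float] = [float(c) for c in fcs]
    else:
        classes = atom_equivalence_classes(mol)
        class_sum: dict[int, float] = {}
        class_cnt: dict[int, int] = {}
        for i, a in enumerate(mol.atoms):
            class_sum[classes[i]] = class_sum.get(classes[i], 0.0) + a.formal_charge
            class_cnt[classes[i]] = class_cnt.get(classes[i], 0) + 1
        sym_fc = [class_sum[classes[i]] / class_cnt[classes[i]] for i in range(n)]

    degrees = [0] * n
    for i, j in mol.bonds:
        degrees[i] += 1
        degrees[j] += 1
    rings = ring_membership(mol) if scheme.include_ring else None

    rows = np.zeros((n, scheme.n_features))
    for i, a in enumerate(mol.atoms):
        col = 0
        rows[i, col + elem_idx[a.element]] = 1.0
        col += len(scheme.elements)
        rows[i, col + min(degrees[i], scheme.max_degree)] = 1.0
        col += scheme.max_degree + 1
        width = scheme.charge_max - scheme.charge_min + 1
        rows[i, col : col + width] = _soft_charge_encoding(
            sym_fc[i], scheme.charge_min, scheme.charge_max
        )
        col += width
        if scheme.include_ring:
            rows[i, col] = 1.0 if rings[i] else 0.0
            col += 1
        if scheme.include_aromatic:
            rows[i, col] = 1.0 if a.aromatic else 0.0
            col += 1
    return rows


@dataclass
class MolGraph:
    """Directed-graph view of one molecule, ready for message passing.

    ``edges`` holds both directions of every bond as an (2E, 2) int array of
    (source, destination) pairs, so a bond contributes one message each way.
    """

    node_features: np.ndarray
    edges: np.ndarray  # (n_directed_edges, 2) int
    num_nodes: int

    @property
    def num_directed_edges(self) -> int:
        return int(self.edges.shape[0])


def build_graph(mol: Molecule, scheme: FeaturizationConfig | None = None) -> MolGraph:
    """Featurize and wire up one molecule as a directed graph."""
    feats = featurize_atoms(mol, scheme)
    if mol.bonds:
        und = np.asarray(mol.bonds, dtype=np.int64)
        edges = np.concatenate([und, und[:, ::-1]], axis=0)
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
    return MolGraph(node_features=feats, edges=edges, num_nodes=mol.num_atoms)


@dataclass
class BatchedGraph:
    """Several molecular graphs with block-diagonal adjacency.

    Node features are stacked, edge indices offset by cumulative node counts
    (so no edge ever crosses a molecule boundary), and ``segment_ids`` maps
    each node back to its molecule. ``total_charges`` carries each molecule's
    Q so the equilibration step can apply the constraint per molecule.
    """

    node_features: np.ndarray
    edges: np.ndarray
    segment_ids: np.ndarray  # (total_nodes,) int, contiguous nondecreasing
    node_counts: np.ndarray  # (n_molecules,) int
    total_charges: np.ndarray  # (n_molecules,) float

    @property
    def num_nodes(self) -> int:
        return int(self.node_features.shape[0])

    @property
    def num_molecules(self) -> int:
        return int(self.node_counts.shape[0])


def batch_graphs(
    graphs: Sequence[MolGraph], charges: Sequence[float] | None = None
) -> BatchedGraph:
    """Concatenate graphs diagonally, preserving molecule order."""
    if len(graphs) == 0:
        raise BatchError("cannot batch an empty sequence of graphs")
    if charges is None:
        charges = [0.0] * len(graphs)
    if len(charges) != len(graphs):
        raise BatchError(
            f"{len(graphs)} graphs but {len(charges)} total charges"
        )
    counts = np.array([g.num_nodes for g in graphs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    feats = np.concatenate([g.node_features for g in graphs], axis=0)
    edge_blocks = [
        g.edges + off for g, off in zip(graphs, offsets) if g.edges.shape[0] > 0
    ]
    edges = (
        np.concatenate(edge_blocks, axis=0)
        if edge_blocks
        else np.zeros((0, 2), dtype=np.int64)
    )
    segment_ids = np.repeat(np.arange(len(graphs), dtype=np.int64), counts)
    return BatchedGraph(
        node_features=feats,
        edges=edges,
        segment_ids=segment_ids,
        node_counts=counts,
        total_charges=np.asarray(charges, dtype=np.float64),
    )


def unbatch(batched: BatchedGraph, per_node_values: np.ndarray) -> list[np.ndarray]:
    """Split a per-node vector (or row-matrix) back into per-molecule pieces."""
    values = np.asarray(per_node_values)
    if values.shape[0] != batched.num_nodes:
        raise DimensionError(
            f"per-node vector has length {values.shape[0]}, batch has "
            f"{batched.num_nodes} nodes"
        )
    split_points = np.cumsum(batched.node_counts)[:-1]
    return [np.array(v) for v in np.split(values, split_points)]
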