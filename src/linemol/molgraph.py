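"""Molecular graphs, molecular line graphs and the knowledge-node augmentation.

A molecule parsed from SMILES becomes an attributed graph G = (V, E) whose
nodes are heavy atoms and whose edges are bonds, each carrying a fixed-length
one-hot/binary feature vector.  The line graph of G has one node per bond and
an edge between two nodes whenever their source bonds share an atom; it is the
input representation of the transformer encoder.  All-pairs shortest-path
structure (hop distances and the node sequences realising them) is computed on
the line graph by breadth-first search and consumed by the encoder's path and
distance attention biases.  Finally a single "knowledge node" carrying a
molecule-level descriptor/fingerprint vector can be appended, connected to
every line-graph node.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "SMILESParseError",
    "FeatureScheme",
    "MolecularGraph",
    "LineGraphNode",
    "LineGraph",
    "AugmentedGraph",
    "parse_smiles",
    "to_line_graph",
    "all_pairs_paths",
    "augment_with_k_node",
    "read_smiles_file",
    "read_smiles_csv",
]

UNREACHABLE = -1  # sentinel hop distance for disconnected node pairs


class SMILESParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""

    def __init__(self, smiles: str, reason: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"cannot parse SMILES {smiles!r}: {reason}")


def _one_hot(value, choices: Sequence) -> np.ndarray:
    """One-hot over ``choices`` with a trailing explicit "other" slot."""
    vec = np.zeros(len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


@dataclass(frozen=True)
class FeatureScheme:
    """Closed vocabularies for atom and bond featurization.

    Unknown categories fall into a dedicated "other" slot, so feature vector
    lengths are fixed for any molecule.
    """

    elements: tuple = ("C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I", "B", "Se")
    degrees: tuple = (0, 1, 2, 3, 4, 5, 6)
    formal_charges: tuple = (-2, -1, 0, 1, 2)
    chiral_tags: tuple = (
        Chem.ChiralType.CHI_UNSPECIFIED,
        Chem.ChiralType.CHI_TETRAHEDRAL_CW,
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    )
    hybridizations: tuple = (
        Chem.HybridizationType.S,
        Chem.HybridizationType.SP,
        Chem.HybridizationType.SP2,
        Chem.HybridizationType.SP3,
        Chem.HybridizationType.SP3D,
        Chem.HybridizationType.SP3D2,
    )
    num_hs: tuple = (0, 1, 2, 3, 4)
    bond_types: tuple = (
        Chem.BondType.SINGLE,
        Chem.BondType.DOUBLE,
        Chem.BondType.TRIPLE,
        Chem.BondType.AROMATIC,
    )
    bond_stereo: tuple = (
        Chem.BondStereo.STEREONONE,
        Chem.BondStereo.STEREOANY,
        Chem.BondStereo.STEREOZ,
        Chem.BondStereo.STEREOE,
        Chem.BondStereo.STEREOCIS,
        Chem.BondStereo.STEREOTRANS,
    )

    @property
    def atom_dim(self) -> int:
        return (
            len(self.elements) + 1 + len(self.degrees) + 1
            + len(self.formal_charges) + 1 + len(self.chiral_tags) + 1
            + len(self.hybridizations) + 1 + 1 + len(self.num_hs) + 1
        )

    @property
    def bond_dim(self) -> int:
        # bond type + conjugated flag + in-ring flag + stereo
        return len(self.bond_types) + 1 + 1 + 1 + len(self.bond_stereo) + 1

    def atom_features(self, atom: Chem.Atom) -> np.ndarray:
        return np.concatenate(
            [
                _one_hot(atom.GetSymbol(), self.elements),
                _one_hot(atom.GetDegree(), self.degrees),
                _one_hot(atom.GetFormalCharge(), self.formal_charges),
                _one_hot(atom.GetChiralTag(), self.chiral_tags),
                _one_hot(atom.GetHybridization(), self.hybridizations),
                np.array([1.0 if atom.GetIsAromatic() else 0.0]),
                _one_hot(atom.GetTotalNumHs(), self.num_hs),
            ]
        )

    def bond_features(self, bond: Chem.Bond) -> np.ndarray:
        return np.concatenate(
            [
                _one_hot(bond.GetBondType(), self.bond_types),
                np.array([1.0 if bond.GetIsConjugated() else 0.0]),
                np.array([1.0 if bond.IsInRing() else 0.0]),
                _one_hot(bond.GetStereo(), self.bond_stereo),
            ]
        )


DEFAULT_SCHEME = FeatureScheme()


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with raw atom/bond feature vectors."""

    atoms: list[np.ndarray]
    bonds: list[tuple[int, int, np.ndarray]]
    n_atoms: int
    smiles_canonical: str
    scheme: FeatureScheme = field(default=DEFAULT_SCHEME, repr=False)
    mol: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self):
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i},{j}) out of range for {self.n_atoms} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)


@dataclass
class LineGraphNode:
    """One line-graph node: a bond of the source graph with its raw triple."""

    bond_index: int
    x_i: np.ndarray  # raw features of one endpoint atom
    x_j: np.ndarray  # raw features of the other endpoint atom
    x_e: np.ndarray  # raw features of the bond itself
    is_masked: bool = False  # set by pre-training corruption, not by construction


@dataclass
class LineGraph:
    nodes: list[LineGraphNode]
    edges: list[tuple[int, int]]
    n_nodes: int
    smiles_canonical: str = ""
    dist: np.ndarray | None = None  # [N, N] hop counts, -1 for unreachable
    paths: list[list[list[int] | None]] | None = None
    # (idx, valid, counts, reach) arrays derived from ``paths`` by
    # all_pairs_paths; consumed by the encoder's path-bias module
    path_arrays: tuple | None = field(default=None, repr=False, compare=False)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(n) for n in adj]


@dataclass
class AugmentedGraph:
    """Line graph plus the knowledge node wired to every base node.

    The knowledge node is excluded from the shortest-path structure: ``dist``
    and ``paths`` of ``base`` describe the un-augmented graph only, and the
    encoder gives knowledge-node pairs a dedicated learned bias instead.
    """

    base: LineGraph
    k_index: int
    knowledge: np.ndarray          # assembled knowledge vector, length 712
    k_edges: list[tuple[int, int]]
    knowledge_mask: np.ndarray | None = None  # indicator of masked entries

    @property
    def n_nodes(self) -> int:
        return self.base.n_nodes + 1


def parse_smiles(smiles: str, scheme: FeatureScheme = DEFAULT_SCHEME) -> MolecularGraph:
    """Parse a SMILES string into an attributed heavy-atom graph.

    Multi-fragment inputs (salts, mixtures) are reduced to their largest
    fragment by heavy-atom count.  Hydrogens remain implicit.

    Raises
    ------
    SMILESParseError
        If the string is empty, syntactically malformed or chemically invalid.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SMILESParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SMILESParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise SMILESParseError(smiles, "no heavy atoms")
    atoms = [scheme.atom_features(a) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), scheme.bond_features(b))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        n_atoms=mol.GetNumAtoms(),
        smiles_canonical=Chem.MolToSmiles(mol),
        scheme=scheme,
        mol=mol,
    )


def to_line_graph(g: MolecularGraph, max_path_nodes: int = 5) -> LineGraph:
    """Build the molecular line graph of ``g`` and fill its path structure.

    One node per bond; two nodes are adjacent iff their source bonds share an
    atom.  A bond-less molecule (single heavy atom) yields a one-node graph
    whose node stores (x_atom, x_atom, zero bond vector) so every molecule
    stays encodable.
    """
    if not g.bonds:
        x = g.atoms[0]
        node = LineGraphNode(0, x.copy(), x.copy(), np.zeros(g.scheme.bond_dim))
        lg = LineGraph([node], [], 1, g.smiles_canonical)
        return all_pairs_paths(lg, max_path_nodes)

    nodes = [
        LineGraphNode(k, g.atoms[i].copy(), g.atoms[j].copy(), x_e.copy())
        for k, (i, j, x_e) in enumerate(g.bonds)
    ]
    endpoints = [(i, j) for i, j, _ in g.bonds]
    edges = []
    for a in range(len(endpoints)):
        sa = set(endpoints[a])
        for b in range(a + 1, len(endpoints)):
            if sa & set(endpoints[b]):
                edges.append((a, b))
    lg = LineGraph(nodes, edges, len(nodes), g.smiles_canonical)
    return all_pairs_paths(lg, max_path_nodes)


def all_pairs_paths(lg: LineGraph, max_path_nodes: int = 5) -> LineGraph:
    """Fill ``lg.dist`` and ``lg.paths`` by breadth-first search from each node.

    Ties are broken by visiting neighbours in ascending index order, so the
    stored shortest paths are deterministic.  Unreachable pairs get distance
    -1 and path ``None``.  Paths longer than ``max_path_nodes`` nodes are
    truncated to their first ``max_path_nodes`` nodes.
    """
    n = lg.n_nodes
    adj = lg.adjacency()
    dist = np.full((n, n), UNREACHABLE, dtype=np.int64)
    paths: list[list[list[int] | None]] = [[None] * n for _ in range(n)]
    for src in range(n):
        dist[src, src] = 0
        parent = {src: None}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    dist[src, v] = dist[src, u] + 1
                    queue.append(v)
        for dst, par in parent.items():
            path = [dst]
            while par is not None:
                path.append(par)
                par = parent[par]
            path.reverse()
            paths[src][dst] = path[:max_path_nodes]
    lg.dist = dist
    lg.paths = paths

    # dense index/mask arrays for the encoder's path-bias module
    idx = np.zeros((n, n, max_path_nodes), dtype=np.intp)
    valid = np.zeros((n, n, max_path_nodes), dtype=float)
    reach = np.zeros((n, n), dtype=float)
    for i in range(n):
        row = paths[i]
        for j in range(n):
            p = row[j]
            if p is None:
                continue
            reach[i, j] = 1.0
            k = len(p)
            idx[i, j, :k] = p
            valid[i, j, :k] = 1.0
    counts = np.maximum(valid.sum(axis=2), 1.0)
    lg.path_arrays = (idx, valid, counts, reach)
    return lg


def augment_with_k_node(lg: LineGraph, knowledge: np.ndarray,
                        expected_dim: int | None = 712) -> AugmentedGraph:
    """Append the knowledge node, connected to every base node.

    The base graph's distance/path structure is left untouched.
    """
    if isinstance(lg, AugmentedGraph):
        raise ValueError("graph already carries a knowledge node")
    knowledge = np.asarray(knowledge, dtype=float)
    if expected_dim is not None and knowledge.shape != (expected_dim,):
        raise ValueError(
            f"knowledge vector has shape {knowledge.shape}, expected ({expected_dim},)"
        )
    k_index = lg.n_nodes
    k_edges = [(k_index, i) for i in range(lg.n_nodes)]
    return AugmentedGraph(base=lg, k_index=k_index, knowledge=knowledge, k_edges=k_edges)


def read_smiles_file(path) -> list[str]:
    """Read a .smi file: one SMILES per line, blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_smiles_csv(path, column: str = "smiles") -> list[str]:
    import pandas as pd

    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"CSV {path} has no {column!r} column")
    return df[column].astype(str).tolist()


# ---------------------------------------------------------------------------
# JSON serialization (fixtures / debugging)

def line_graph_to_json(lg: LineGraph) -> str:
    payload = {
        "smiles": lg.smiles_canonical,
        "n_nodes": lg.n_nodes,
        "edges": [list(e) for e in lg.edges],
        "nodes": [
            {
                "bond_index": nd.bond_index,
                "x_i": nd.x_i.tolist(),
                "x_j": nd.x_j.tolist(),
                "x_e": nd.x_e.tolist(),
            }
            for nd in lg.nodes
        ],
        "dist": lg.dist.tolist() if lg.dist is not None else None,
    }
    return json.dumps(payload)


def line_graph_from_json(text: str) -> LineGraph:
    payload = json.loads(text)
    nodes = [
        LineGraphNode(
            nd["bond_index"],
            np.array(nd["x_i"], dtype=float),
            np.array(nd["x_j"], dtype=float),
            np.array(nd["x_e"], dtype=float),
        )
        for nd in payload["nodes"]
    ]
    lg = LineGraph(
        nodes,
        [tuple(e) for e in payload["edges"]],
        payload["n_nodes"],
        payload["smiles"],
    )
    if payload.get("dist") is not None:
        lg.dist = np.array(payload["dist"], dtype=np.int64)
    return lg
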