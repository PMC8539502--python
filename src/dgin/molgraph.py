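"""SMILES parsing and directed, featurized molecular graphs.

Molecules are perceived with RDKit (aromaticity, ring membership, implicit
hydrogens) and turned into directed heterogeneous graphs: every chemical bond
u-v contributes the two directed edges ``u->v`` and ``v->u``, each carrying an
identical bond feature vector.  Node and edge feature vectors are assembled
from declarative *feature blocks* so the six featurization strategies are pure
data — adding or swapping a block never touches graph construction code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Fixed element vocabulary; the trailing slot catches everything else.
ELEMENTS = ("H", "C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
OTHER_ELEMENT = "other"

FORMAL_CHARGES = (-2, -1, 0, 1, 2)
HYBRIDIZATIONS = ("SP", "SP2", "SP3", "other")
MAX_DEGREE = 5       # one-hot 0..5, clamped
MAX_H_COUNT = 4      # one-hot 0..4, clamped
BOND_ORDERS = ("single", "double", "triple", "aromatic")
# one-hot instances for ring size; 0 = not in a ring, >11 clamps to 11
RING_SIZE_INSTANCES = (0, 3, 4, 5, 6, 7, 8, 9, 10, 11)


class ParseError(ValueError):
    """Raised when a SMILES string cannot be perceived."""


class UnknownElementError(ValueError):
    """Raised for an element outside the supported vocabulary (strict mode)."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    in_ring: bool
    smallest_ring_size: int  # 0 iff not in a ring
    hybridization: str
    degree: int              # heavy-atom degree
    h_count: int             # total (implicit + explicit) hydrogens


@dataclass(frozen=True)
class Bond:
    u: int
    v: int
    order: str               # one of BOND_ORDERS
    in_ring: bool
    conjugated: bool


@dataclass(frozen=True)
class Molecule:
    """Perceived heavy-atom structure: dense atom indices, undirected bonds."""

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a perceived :class:`Molecule`.

    Hydrogens stay implicit (heavy-atom graph); aromaticity and ring
    perception follow RDKit's sanitization.  Raises :class:`ParseError`
    naming the input on malformed SMILES.
    """
    from rdkit import Chem

    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return _from_rdkit(rdmol, smiles)


def _from_rdkit(rdmol, smiles: str = "") -> Molecule:
    from rdkit import Chem

    ring_info = rdmol.GetRingInfo()
    atom_rings = ring_info.AtomRings()
    bond_order_map = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    atoms = []
    for a in rdmol.GetAtoms():
        idx = a.GetIdx()
        sizes = [len(r) for r in atom_rings if idx in r]
        hyb = str(a.GetHybridization())
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                in_ring=bool(sizes),
                smallest_ring_size=min(sizes) if sizes else 0,
                hybridization=hyb if hyb in HYBRIDIZATIONS else "other",
                degree=a.GetDegree(),
                h_count=a.GetTotalNumHs(),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = bond_order_map.get(b.GetBondType())
        if order is None:
            raise ParseError(
                f"unsupported bond type {b.GetBondType()} in SMILES {smiles!r}"
            )
        bonds.append(
            Bond(
                u=b.GetBeginAtomIdx(),
                v=b.GetEndAtomIdx(),
                order=order,
                in_ring=b.IsInRing(),
                conjugated=b.GetIsConjugated(),
            )
        )
    return Molecule(atoms=tuple(atoms), bonds=tuple(bonds), smiles=smiles)


# ---------------------------------------------------------------------------
# Ring-size encodings
# ---------------------------------------------------------------------------

def ring_size_float(smallest_ring_size: int) -> float:
    """Encode ring size as ``1/size``; non-ring atoms (size 0) map to 0.0."""
    if smallest_ring_size == 0:
        return 0.0
    if smallest_ring_size < 3:
        raise ValueError(f"invalid ring size {smallest_ring_size}; rings have >= 3 atoms")
    return 1.0 / smallest_ring_size


def ring_size_onehot(smallest_ring_size: int) -> np.ndarray:
    """One-hot over the instances (0,3,4,...,11); sizes above 11 clamp to 11."""
    if smallest_ring_size < 0 or smallest_ring_size in (1, 2):
        raise ValueError(f"invalid ring size {smallest_ring_size}")
    vec = np.zeros(len(RING_SIZE_INSTANCES))
    if smallest_ring_size > 11:
        vec[-1] = 1.0
    else:
        vec[RING_SIZE_INSTANCES.index(smallest_ring_size)] = 1.0
    return vec


# ---------------------------------------------------------------------------
# Feature blocks
# ---------------------------------------------------------------------------

def _onehot(value, choices, clamp: bool = False) -> np.ndarray:
    vec = np.zeros(len(choices))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif clamp:
        vec[-1] = 1.0
    else:
        raise ValueError(f"value {value!r} not in {choices}")
    return vec


def _element_block(atom: Atom, permissive: bool) -> np.ndarray:
    vocab = ELEMENTS + (OTHER_ELEMENT,)
    if atom.element in ELEMENTS:
        return _onehot(atom.element, vocab)
    if not permissive:
        raise UnknownElementError(
            f"element {atom.element!r} outside supported vocabulary {ELEMENTS}"
        )
    logger.warning("element %r mapped to %r slot", atom.element, OTHER_ELEMENT)
    vec = np.zeros(len(vocab))
    vec[-1] = 1.0
    return vec


# name -> (length, fn(atom, permissive) -> vector)
NODE_BLOCKS = {
    "element": (len(ELEMENTS) + 1, _element_block),
    "formal_charge": (
        len(FORMAL_CHARGES),
        lambda a, p: _onehot(
            int(np.clip(a.formal_charge, FORMAL_CHARGES[0], FORMAL_CHARGES[-1])),
            list(FORMAL_CHARGES),
        ),
    ),
    "aromatic": (1, lambda a, p: np.array([float(a.aromatic)])),
    "hybridization": (
        len(HYBRIDIZATIONS),
        lambda a, p: _onehot(a.hybridization, list(HYBRIDIZATIONS), clamp=True),
    ),
    "degree": (
        MAX_DEGREE + 1,
        lambda a, p: _onehot(min(a.degree, MAX_DEGREE), list(range(MAX_DEGREE + 1))),
    ),
    "h_count": (
        MAX_H_COUNT + 1,
        lambda a, p: _onehot(min(a.h_count, MAX_H_COUNT), list(range(MAX_H_COUNT + 1))),
    ),
    "in_ring": (1, lambda a, p: np.array([float(a.in_ring)])),
    "ring_size_float": (1, lambda a, p: np.array([ring_size_float(a.smallest_ring_size)])),
    "ring_size_onehot": (
        len(RING_SIZE_INSTANCES),
        lambda a, p: ring_size_onehot(a.smallest_ring_size),
    ),
}

EDGE_BLOCKS = {
    "bond_order": (len(BOND_ORDERS), lambda b: _onehot(b.order, list(BOND_ORDERS))),
    "conjugated": (1, lambda b: np.array([float(b.conjugated)])),
    "in_ring": (1, lambda b: np.array([float(b.in_ring)])),
}

_FULL_NODE_FLOAT = (
    "element", "formal_charge", "aromatic", "hybridization",
    "degree", "h_count", "in_ring", "ring_size_float",
)
_FULL_NODE_ONEHOT = (
    "element", "formal_charge", "aromatic", "hybridization",
    "degree", "h_count", "in_ring", "ring_size_onehot",
)
_FULL_EDGE = ("bond_order", "conjugated", "in_ring")
_MINIMAL_NODE = ("element", "formal_charge")
_MINIMAL_EDGE = ("bond_order",)
# reduced set: the five node / three edge blocks retained after ablation,
# ring size among them
_REDUCED_NODE = ("element", "formal_charge", "aromatic", "h_count", "ring_size_float")


@dataclass(frozen=True)
class FeaturizationStrategy:
    """A named node/edge feature schema.

    ``d`` and ``b`` are the total node and edge vector lengths; the schemas
    are ordered block-name tuples resolved against the block registries.
    """

    id: int
    node_schema: tuple[str, ...]
    edge_schema: tuple[str, ...]

    @property
    def d(self) -> int:
        return sum(NODE_BLOCKS[name][0] for name in self.node_schema)

    @property
    def b(self) -> int:
        return sum(EDGE_BLOCKS[name][0] for name in self.edge_schema)

    def node_block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name in self.node_schema:
            length = NODE_BLOCKS[name][0]
            out[name] = slice(start, start + length)
            start += length
        return out

    def edge_block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name in self.edge_schema:
            length = EDGE_BLOCKS[name][0]
            out[name] = slice(start, start + length)
            start += length
        return out


STRATEGIES: dict[int, FeaturizationStrategy] = {
    3: FeaturizationStrategy(3, _FULL_NODE_FLOAT, _FULL_EDGE),
    4: FeaturizationStrategy(4, _FULL_NODE_ONEHOT, _FULL_EDGE),
    5: FeaturizationStrategy(5, _MINIMAL_NODE, _MINIMAL_EDGE),
    6: FeaturizationStrategy(6, _MINIMAL_NODE, _FULL_EDGE),
    7: FeaturizationStrategy(7, _FULL_NODE_FLOAT, _MINIMAL_EDGE),
    8: FeaturizationStrategy(8, _REDUCED_NODE, _FULL_EDGE),
}


def get_strategy(strategy_id: int) -> FeaturizationStrategy:
    try:
        return STRATEGIES[strategy_id]
    except KeyError:
        raise ValueError(f"unknown featurization strategy {strategy_id}; valid: 3..8")


def featurize_node(
    atom: Atom, strategy: FeaturizationStrategy, permissive: bool = False
) -> np.ndarray:
    """Assemble one atom's feature vector of length ``strategy.d``."""
    return np.concatenate(
        [NODE_BLOCKS[name][1](atom, permissive) for name in strategy.node_schema]
    )


def featurize_edge(bond: Bond, strategy: FeaturizationStrategy) -> np.ndarray:
    """Assemble one bond's feature vector of length ``strategy.b``.

    Both directed edges of a bond receive this same vector.
    """
    return np.concatenate([EDGE_BLOCKS[name][1](bond) for name in strategy.edge_schema])


# ---------------------------------------------------------------------------
# Directed graphs
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Directed molecular graph with per-node and per-directed-edge features.

    Directed edges come in reverse pairs: edge ``2i`` is ``u->v`` and edge
    ``2i+1`` is ``v->u`` for bond ``i``, so the reverse of edge ``e`` is
    ``e ^ 1``.
    """

    n: int
    src: np.ndarray          # (m,) int, source node of each directed edge
    dst: np.ndarray          # (m,) int, target node
    X: np.ndarray            # (n, d) node features
    E: np.ndarray            # (m, b) directed-edge features
    strategy_id: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def reverse_edge(self, e: int) -> int:
        return e ^ 1

    @property
    def adjacency(self) -> np.ndarray:
        """Binary n x n adjacency; symmetric because edges come in pairs."""
        A = np.zeros((self.n, self.n), dtype=np.int8)
        A[self.src, self.dst] = 1
        return A

    def neighbors(self, u: int) -> np.ndarray:
        """Neighbors of u (targets of edges leaving u), sorted."""
        return np.sort(self.dst[self.src == u])


def build_graph(
    mol: Molecule,
    strategy: FeaturizationStrategy | int,
    permissive: bool = False,
) -> MolecularGraph:
    """Build the directed featurized graph of a molecule.

    Every bond yields the two directed edges ``u->v`` and ``v->u`` with
    identical feature vectors; node features follow the strategy schema.
    """
    if isinstance(strategy, int):
        strategy = get_strategy(strategy)
    n = mol.n_atoms
    X = (
        np.stack([featurize_node(a, strategy, permissive) for a in mol.atoms])
        if n
        else np.zeros((0, strategy.d))
    )
    src, dst, feats = [], [], []
    for bond in mol.bonds:
        vec = featurize_edge(bond, strategy)
        src += [bond.u, bond.v]
        dst += [bond.v, bond.u]
        feats += [vec, vec]
    E = np.stack(feats) if feats else np.zeros((0, strategy.b))
    return MolecularGraph(
        n=n,
        src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64),
        X=X,
        E=E,
        strategy_id=strategy.id,
    )


def graph_from_smiles(
    smiles: str, strategy: FeaturizationStrategy | int, permissive: bool = False
) -> MolecularGraph:
    return build_graph(parse_molecule(smiles), strategy, permissive)
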