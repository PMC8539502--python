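import numpy as np
import pytest

from dgin.gnn import GraphBatch
from dgin.molgraph import MolecularGraph, build_graph, parse_molecule
from dgin.synthetic import generate_library


def make_graph(n: int, bonds: list[tuple[int, int]], d: int = 4, b: int = 3,
               rng=None) -> MolecularGraph:
    """Hand-built directed graph with random (or uniform) features."""
    src, dst = [], []
    for u, v in bonds:
        src += [u, v]
        dst += [v, u]
    if rng is None:
        X = np.ones((n, d))
        E = np.ones((len(src), b))
    else:
        X = rng.normal(size=(n, d))
        E_half = rng.normal(size=(len(bonds), b))
        E = np.repeat(E_half, 2, axis=0)  # both directions share features
    return MolecularGraph(n=n, src=np.array(src, dtype=np.int64),
                          dst=np.array(dst, dtype=np.int64), X=X, E=E)


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes: new id of old node u is perm[u]."""
    inv = np.argsort(perm)
    return MolecularGraph(
        n=g.n,
        src=perm[g.src],
        dst=perm[g.dst],
        X=g.X[inv],
        E=g.E.copy(),
        strategy_id=g.strategy_id,
    )


@pytest.fixture(scope="session")
def small_molecules():
    """A mixed bag of parsed molecules for schema-wide checks."""
    smiles = ["C", "CC", "c1ccccc1", "CC(=O)O", "C1CC1", "N#Cc1ccccc1",
              "OCC(N)C(=O)O", "C1CCCCC1CBr", "[O-]C(=O)C", "CSC"]
    return [parse_molecule(s) for s in smiles]


@pytest.fixture(scope="session")
def random_small_graphs():
    """25 random molecules with at most 8 heavy atoms, strategy-3 graphs."""
    smiles = generate_library(25, seed=11, max_atoms=8)
    return [build_graph(parse_molecule(s), 3) for s in smiles]


@pytest.fixture
def batch_of(random_small_graphs):
    return GraphBatch.from_graphs(random_small_graphs[:4])
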