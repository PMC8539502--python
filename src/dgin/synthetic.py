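"""Synthetic molecule libraries with additive ground-truth properties.

The generator samples random heavy-atom trees over C/N/O/S (optionally closed
into a single ring) and labels them with properties built from known additive
contributions: a per-element term, a per-bond-order term and a ring bonus,
plus Gaussian noise.  The three labels mimic the correlation structure of
lipophilicity/solubility data: the distribution coefficient follows the
partition coefficient minus an ionizable-nitrogen penalty, and solubility is
anticorrelated with lipophilicity.  Because the target is an exact sum over
atoms and bonds, a sum-pooling graph network can represent it exactly, which
makes parameter-recovery training runs a sharp correctness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .molgraph import Molecule, parse_molecule

# Max valence budget used while growing trees (heavy neighbors only).
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENT_CHOICES = ("C", "C", "C", "C", "N", "O", "S")  # carbon-rich draw


@dataclass(frozen=True)
class SyntheticTheta:
    """Ground-truth additive contributions for synthetic properties."""

    atom_contrib: dict = field(
        default_factory=lambda: {"C": 0.5, "N": -0.7, "O": -0.9, "S": 0.2}
    )
    bond_contrib: dict = field(
        default_factory=lambda: {"single": 0.1, "double": 0.25,
                                 "triple": 0.3, "aromatic": 0.15}
    )
    ring_bonus: float = 0.4
    noise_sigma: float = 0.1
    # logS = a * logP + b (+ noise), anticorrelated: a < 0
    coupling_a: float = -1.0
    coupling_b: float = -2.0
    # logD = logP - charge_penalty * (# nitrogen atoms), an ionization proxy
    charge_penalty: float = 0.3

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def generate_library(n: int, seed: int, max_atoms: int = 12) -> list[str]:
    """Sample ``n`` valid SMILES of random heavy-atom trees (C/N/O/S) with an
    optional single ring closure.  Fully seeded; every output re-parses."""
    from rdkit import Chem

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        n_atoms = int(rng.integers(1, max_atoms + 1))
        elements = [str(rng.choice(_ELEMENT_CHOICES)) for _ in range(n_atoms)]
        free = [_VALENCE[e] for e in elements]
        mol = Chem.RWMol()
        for e in elements:
            mol.AddAtom(Chem.Atom(e))
        edges = set()
        ok = True
        for i in range(1, n_atoms):
            candidates = [j for j in range(i) if free[j] >= 1]
            if not candidates:
                ok = False
                break
            j = int(rng.choice(candidates))
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            edges.add((min(i, j), max(i, j)))
            free[i] -= 1
            free[j] -= 1
        if not ok:
            continue
        # close one ring with probability 1/2 when a valid non-adjacent pair exists
        if n_atoms >= 3 and rng.random() < 0.5:
            pairs = [
                (i, j)
                for i in range(n_atoms)
                for j in range(i + 1, n_atoms)
                if free[i] >= 1 and free[j] >= 1 and (i, j) not in edges
            ]
            if pairs:
                i, j = pairs[int(rng.integers(len(pairs)))]
                mol.AddBond(i, j, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - tree construction keeps valences legal
            continue
        smi = Chem.MolToSmiles(mol)
        reparsed = Chem.MolFromSmiles(smi)
        if reparsed is None:
            continue
        # keep the library saturated: reject draws whose small heteroatom
        # rings re-perceive as aromatic, so bond orders stay homogeneous
        if any(b.GetIsAromatic() for b in reparsed.GetBonds()):
            continue
        out.append(smi)
    return out


def assign_properties(
    mol: Molecule, theta: SyntheticTheta, seed: int
) -> tuple[float, float, float]:
    """Label one molecule: returns (logP, logD, logS) synthetic values.

    logP is the additive composition score plus Normal(0, sigma); logD
    subtracts the nitrogen penalty; logS couples linearly to logP with its
    own independent noise draw.
    """
    rng = np.random.default_rng(seed)
    base = sum(theta.atom_contrib.get(a.element, 0.0) for a in mol.atoms)
    base += sum(theta.bond_contrib.get(b.order, 0.0) for b in mol.bonds)
    if any(a.in_ring for a in mol.atoms):
        base += theta.ring_bonus
    logp = base + rng.normal(0.0, theta.noise_sigma)
    n_nitrogen = sum(a.element == "N" for a in mol.atoms)
    logd = logp - theta.charge_penalty * n_nitrogen
    logs = (theta.coupling_a * logp + theta.coupling_b
            + rng.normal(0.0, theta.noise_sigma))
    return float(logp), float(logd), float(logs)


def generate_dataset(
    n: int,
    seed: int,
    theta: SyntheticTheta | None = None,
    max_atoms: int = 12,
):
    """Full labeled dataset as a pandas DataFrame (smiles, logd, logs, logp)."""
    import pandas as pd

    theta = theta or SyntheticTheta()
    smiles = generate_library(n, seed, max_atoms)
    rows = []
    for i, smi in enumerate(smiles):
        mol = parse_molecule(smi)
        logp, logd, logs = assign_properties(mol, theta, seed=seed * 100003 + i)
        rows.append({"smiles": smi, "logd": logd, "logs": logs, "logp": logp})
    return pd.DataFrame(rows)


def write_dataset(path: str | Path, n: int, seed: int,
                  theta: SyntheticTheta | None = None, max_atoms: int = 12):
    """Write the dataset CSV plus a manifest JSON recording theta and seed."""
    theta = theta or SyntheticTheta()
    path = Path(path)
    df = generate_dataset(n, seed, theta, max_atoms)
    df.to_csv(path, index=False)
    manifest = {"n": n, "seed": seed, "max_atoms": max_atoms,
                "theta": asdict(theta)}
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return df


# ---------------------------------------------------------------------------
# The 1-WL motivating pair
# ---------------------------------------------------------------------------

def wl_pair():
    """Naphthalene vs 1,1-bi(cyclopentane) skeletons with uniform features.

    Both graphs have 10 nodes, 11 bonds and the same degree multiset, yet are
    non-isomorphic; 1-WL-bounded networks that ignore edge direction collapse
    them.  Node and edge features are uniform (all ones) so topology is the
    only distinguishing signal.  Returns two :class:`MolecularGraph`-like
    objects with d = b = 1.
    """
    from .molgraph import MolecularGraph

    # naphthalene skeleton: two fused 6-cycles sharing edge (0, 5)
    naph_bonds = [
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
        (5, 6), (6, 7), (7, 8), (8, 9), (9, 0),
    ]
    # 1,1-bi(cyclopentane) skeleton: two 5-cycles joined by the bond (0, 5)
    bicp_bonds = [
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
        (5, 6), (6, 7), (7, 8), (8, 9), (9, 5),
        (0, 5),
    ]

    def build(bonds):
        src, dst = [], []
        for u, v in bonds:
            src += [u, v]
            dst += [v, u]
        m = len(src)
        return MolecularGraph(
            n=10,
            src=np.asarray(src, dtype=np.int64),
            dst=np.asarray(dst, dtype=np.int64),
            X=np.ones((10, 1)),
            E=np.ones((m, 1)),
            strategy_id=0,
        )

    return build(naph_bonds), build(bicp_bonds)
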