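"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: subgraph search is done
with networkx graph matching, Spearman correlation with explicit
rank-then-Pearson, and Kabsch superposition with a direct SVD.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem
from scipy.stats import rankdata


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetAtomicNum())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   bt=bond.GetBondType())
    return g


def _embeds_in(sub: nx.Graph, host: nx.Graph) -> bool:
    gm = GraphMatcher(host, sub,
                      node_match=lambda a, b: a["el"] == b["el"],
                      edge_match=lambda a, b: a["bt"] == b["bt"])
    return gm.subgraph_is_monomorphic()


def bruteforce_mcs(smiles_a: str, smiles_b: str) -> tuple[int, set[int]]:
    """Largest common connected substructure of two small molecules.

    Enumerates every connected bond subset of molecule A (via RDKit's
    subgraph enumeration) and keeps those that embed into B as a subgraph
    monomorphism with element/bond-order matching. Returns the maximum
    common bond count and the set of atom counts achieved at that bond
    count (co-optimal solutions may differ in atoms).
    """
    mol_a = Chem.MolFromSmiles(smiles_a)
    mol_b = Chem.MolFromSmiles(smiles_b)
    g_a, g_b = mol_graph(mol_a), mol_graph(mol_b)
    for n_bonds in range(mol_a.GetNumBonds(), 0, -1):
        atom_counts: set[int] = set()
        for bond_ids in Chem.FindAllSubgraphsOfLengthN(mol_a, n_bonds):
            atoms: set[int] = set()
            edges = []
            for bid in bond_ids:
                bond = mol_a.GetBondWithIdx(bid)
                i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                atoms |= {i, j}
                edges.append((i, j))
            sub = nx.Graph()
            for a in atoms:
                sub.add_node(a, el=g_a.nodes[a]["el"])
            for i, j in edges:
                sub.add_edge(i, j, bt=g_a.edges[i, j]["bt"])
            if _embeds_in(sub, g_b):
                atom_counts.add(len(atoms))
        if atom_counts:
            return n_bonds, atom_counts
    return 0, {0}


def spearman_rho_oracle(matrix: np.ndarray) -> np.ndarray:
    """Row-pairwise Spearman correlation as rank-transform then Pearson."""
    ranks = np.vstack([rankdata(row) for row in matrix])
    n = ranks.shape[0]
    rho = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            rho[i, j] = np.corrcoef(ranks[i], ranks[j])[0, 1]
    return rho


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD of two point sets after optimal rigid superposition (2D)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0] * (P.shape[1] - 1) + [d])
    R = Vt.T @ D @ U.T
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
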