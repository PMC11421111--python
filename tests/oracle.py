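"""Independent brute-force substructure matcher used as a test oracle.

Builds plain graphs from SMILES and searches for a subgraph monomorphism
with networkx (exhaustive backtracking), entirely independent of the
package's RDKit-query matching route. Atom compatibility: same element,
same aromatic flag, same formal charge, same isotope, and the target atom
must carry at least as many hydrogens as the pattern atom has written
``[H]`` neighbours. Bond compatibility: identical bond type.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

_KEEP_H = Chem.SmilesParserParams()
_KEEP_H.removeHs = False


def _pattern_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles, _KEEP_H)
    assert mol is not None, smiles
    min_h: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            nb = atom.GetNeighbors()[0].GetIdx()
            min_h[nb] = min_h.get(nb, 0) + 1
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        g.add_node(
            atom.GetIdx(),
            z=atom.GetAtomicNum(),
            arom=atom.GetIsAromatic(),
            charge=atom.GetFormalCharge(),
            isotope=atom.GetIsotope(),
            min_h=min_h.get(atom.GetIdx(), 0),
        )
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        g.add_edge(a.GetIdx(), b.GetIdx(), order=str(bond.GetBondType()))
    return g


def _target_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            z=atom.GetAtomicNum(),
            arom=atom.GetIsAromatic(),
            charge=atom.GetFormalCharge(),
            isotope=atom.GetIsotope(),
            n_h=atom.GetTotalNumHs(),
        )
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType()))
    return g


def brute_force_match(pattern_smiles: str, target_smiles: str) -> bool:
    """True iff an embedding of the pattern into the target exists."""
    pg = _pattern_graph(pattern_smiles)
    tg = _target_graph(target_smiles)

    def node_match(t, p):
        return (
            t["z"] == p["z"]
            and t["arom"] == p["arom"]
            and t["charge"] == p["charge"]
            and t["isotope"] == p["isotope"]
            and t["n_h"] >= p["min_h"]
        )

    def edge_match(t, p):
        return t["order"] == p["order"]

    gm = nx.algorithms.isomorphism.GraphMatcher(tg, pg, node_match=node_match, edge_match=edge_match)
    return gm.subgraph_is_monomorphic()
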