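"""Substructure query compilation and matching with defined-hydrogen semantics.

Catalog patterns are plain SMILES that may contain explicitly written ``[H]``
atoms. A written hydrogen marks a position that must stay unsubstituted in a
match ("irreplaceable"); every unwritten hydrogen is substitutable by any
atom. Compilation turns each pattern into an RDKit query molecule whose atoms
constrain element, aromatic/aliphatic state, exact formal charge, exact
isotope, and — for atoms carrying written hydrogens — a minimum total
hydrogen count. Stereochemistry is stripped from both patterns and targets'
role in matching (patterns are 2D).

The same machinery drives basic-scaffold detection: a scaffold is "present"
iff its core is a substructure of the molecule, with no ring-system pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdqueries

if TYPE_CHECKING:  # pragma: no cover
    from .chem_io import CompoundRecord, ScaffoldDef, SubstructureRecord


class PatternCompileError(Exception):
    """Raised when a catalog SMILES cannot be turned into a query."""


#: the five basic-scaffold cores used as the library pre-filter
BASIC_SCAFFOLDS: tuple[tuple[str, str], ...] = (
    ("chromone", "O=C1C=COc2ccccc21"),
    ("xanthone", "O=C1c2ccccc2Oc2ccccc21"),
    ("phenothiazine", "N1c2ccccc2Sc2ccccc21"),
    ("purine", "c1ncc2[nH]cnc2n1"),
    ("9-deazapurine", "c1ncc2[nH]ccc2n1"),
)

_PARSE_KEEP_H = Chem.SmilesParserParams()
_PARSE_KEEP_H.removeHs = False

_AND = Chem.CompositeQueryType.COMPOSITE_AND


@dataclass
class PatternQuery:
    """A compiled pattern plus its hydrogen/heavy-atom accounting.

    ``flexibility`` is the pattern's count of substitutable (non-defined)
    hydrogens divided by its heavy-atom count; low values mark structurally
    specific patterns. A fully hydrogen-defined pattern has flexibility 0.
    """

    substructure_id: str
    smiles: str
    query: Chem.Mol = field(repr=False, compare=False)
    n_heavy: int = 0
    n_H_total: int = 0
    n_H_defined: int = 0

    @property
    def n_H_variable(self) -> int:
        return self.n_H_total - self.n_H_defined

    @property
    def flexibility(self) -> float:
        return self.n_H_variable / self.n_heavy


def _build_query(mol_with_h: Chem.Mol) -> tuple[Chem.Mol, dict[str, int]]:
    """Build the query molecule and the H/heavy accounting from a pattern
    parsed with explicit hydrogens retained."""
    min_h: dict[int, int] = {}
    for atom in mol_with_h.GetAtoms():
        if atom.GetAtomicNum() == 1:
            if atom.GetDegree() != 1:
                raise PatternCompileError("defined [H] must be bonded to exactly one heavy atom")
            nb = atom.GetNeighbors()[0]
            if nb.GetAtomicNum() == 1:
                raise PatternCompileError("H-H bond in pattern")
            min_h[nb.GetIdx()] = min_h.get(nb.GetIdx(), 0) + 1

    heavy_idx = [a.GetIdx() for a in mol_with_h.GetAtoms() if a.GetAtomicNum() != 1]
    if not heavy_idx:
        raise PatternCompileError("pattern has no heavy atoms")
    # total H = implicit/bracket H plus written [H] neighbours, per heavy atom
    n_h_total = sum(
        mol_with_h.GetAtomWithIdx(i).GetTotalNumHs(includeNeighbors=True) for i in heavy_idx
    )
    n_h_defined = sum(min_h.values())

    heavy = Chem.RemoveHs(mol_with_h)  # folds written H into the implicit count
    rw = Chem.RWMol(heavy)
    for atom in heavy.GetAtoms():
        i = atom.GetIdx()
        qa = rdqueries.AtomNumEqualsQueryAtom(atom.GetAtomicNum())
        qa.ExpandQuery(
            rdqueries.IsAromaticQueryAtom() if atom.GetIsAromatic() else rdqueries.IsAliphaticQueryAtom(),
            _AND,
        )
        qa.ExpandQuery(rdqueries.FormalChargeEqualsQueryAtom(atom.GetFormalCharge()), _AND)
        qa.ExpandQuery(rdqueries.IsotopeEqualsQueryAtom(atom.GetIsotope()), _AND)
        n = min_h.get(heavy_idx[i], 0)
        if n > 0:
            qa.ExpandQuery(rdqueries.HCountGreaterQueryAtom(n - 1), _AND)  # total H >= n
        rw.ReplaceAtom(i, qa, preserveProps=True)
    acct = {
        "n_heavy": len(heavy_idx),
        "n_H_total": int(n_h_total),
        "n_H_defined": int(n_h_defined),
    }
    return rw.GetMol(), acct


def compile_pattern(record: "SubstructureRecord") -> PatternQuery:
    """Compile a catalog record (or anything with ``substructure_id`` and
    ``smiles``) into a :class:`PatternQuery`."""
    mol = Chem.MolFromSmiles(record.smiles, _PARSE_KEEP_H)
    if mol is None:
        raise PatternCompileError(
            f"substructure {record.substructure_id!r}: unparseable SMILES {record.smiles!r}"
        )
    Chem.RemoveStereochemistry(mol)
    try:
        query, acct = _build_query(mol)
    except PatternCompileError as exc:
        raise PatternCompileError(f"substructure {record.substructure_id!r}: {exc}") from exc
    return PatternQuery(
        substructure_id=record.substructure_id,
        smiles=record.smiles,
        query=query,
        **acct,
    )


def compile_smiles(substructure_id: str, smiles: str) -> PatternQuery:
    """Convenience wrapper: compile a bare (id, SMILES) pair."""
    from .chem_io import SubstructureRecord

    return compile_pattern(SubstructureRecord(substructure_id, "", smiles))


def matches(query: PatternQuery, mol: Chem.Mol) -> bool:
    """True iff an embedding of the query into ``mol`` exists honoring
    element, aromaticity, bond order, charge, isotope and defined-H
    constraints. Multiple embeddings count once (pure presence predicate)."""
    target = Chem.Mol(mol)
    Chem.RemoveStereochemistry(target)
    return target.HasSubstructMatch(query.query)


@dataclass
class OccurrenceMatrix:
    """Boolean compounds × substructures presence matrix."""

    compound_ids: list[str]
    substructure_ids: list[str]
    presence: np.ndarray  # bool, shape (n_compounds, n_substructures)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.compound_ids), len(self.substructure_ids)):
            raise ValueError("presence matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.compound_ids, columns=self.substructure_ids)

    def column_counts(self) -> pd.Series:
        return self.to_frame().sum(axis=0)


def occurrence_matrix(
    compounds: Sequence["CompoundRecord"], patterns: Sequence[PatternQuery]
) -> OccurrenceMatrix:
    """Presence/absence of every pattern in every compound."""
    presence = np.zeros((len(compounds), len(patterns)), dtype=bool)
    for j, pat in enumerate(patterns):
        for i, rec in enumerate(compounds):
            presence[i, j] = matches(pat, rec.mol)
    return OccurrenceMatrix(
        compound_ids=[c.compound_id for c in compounds],
        substructure_ids=[p.substructure_id for p in patterns],
        presence=presence,
    )


def compile_scaffolds(scaffolds: Iterable["ScaffoldDef"]) -> list[PatternQuery]:
    return [compile_smiles(s.scaffold_name, s.smiles) for s in scaffolds]


def detect_scaffolds(mol: Chem.Mol, scaffolds: Sequence) -> set[str]:
    """All scaffold names whose core is a substructure of ``mol``.

    Accepts either :class:`~patternscore.chem_io.ScaffoldDef` items (compiled
    on the fly) or pre-compiled :class:`PatternQuery` items. A molecule may
    carry two or more scaffolds; all are reported.
    """
    compiled = [
        s if isinstance(s, PatternQuery) else compile_smiles(s.scaffold_name, s.smiles)
        for s in scaffolds
    ]
    return {q.substructure_id for q in compiled if matches(q, mol)}


def default_scaffold_defs() -> list:
    """The five built-in basic-scaffold definitions."""
    from .chem_io import ScaffoldDef

    return [ScaffoldDef(name, smi) for name, smi in BASIC_SCAFFOLDS]
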