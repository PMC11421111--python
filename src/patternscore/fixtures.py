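"""Synthetic compound sets, catalogs, and screening libraries with known
ground truth.

Molecules are assembled from a template grammar: an optional scaffold core
plus decoration fragments joined by single bonds at positions with free
valence. Planted substructures are attached to exactly ``round(freq * n)``
compounds, so fingerprint values are known in advance. The decoration pool
is deliberately bland (saturated C/O fragments) to avoid accidentally
producing a planted pattern; the generator nevertheless verifies every
molecule post hoc with the real matcher and redraws on collision (bounded
retries), so the shipped ground truth is exact by construction, not by hope.

What this emulates: the *structure* of a curated bioactivity dataset —
unequal class sizes, patterns shared within and across classes, scaffold
carriers mixed with scaffold-free compounds. What it does not emulate:
drug-likeness, realistic substituent chemistry, or the redundancy patterns
of literature-derived analog series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, SubstructureRecord, canonical_smiles
from .pattern_engine import (
    BASIC_SCAFFOLDS,
    PatternQuery,
    compile_smiles,
    matches,
)


class FixtureError(Exception):
    """Infeasible fixture spec or exhausted redraw budget."""


#: bland decoration fragments; saturated C/O only so that typical planted
#: patterns (aromatics, amines, amides) cannot arise by accident
DECORATIONS: tuple[str, ...] = (
    "CC",
    "CCC",
    "CCO",
    "CC(C)C",
    "CCOC",
    "CC(C)O",
    "C1CCCCC1",
    "CCCCO",
)

_MAX_RETRIES = 30


@dataclass(frozen=True)
class PlantedPattern:
    smiles: str
    frequency: float
    restrict_to_classes: tuple[str, ...] | None = None


@dataclass
class FixtureSpec:
    """Recipe for a synthetic compound set; the seed fully determines it."""

    n_compounds: int
    classes: tuple[tuple[str, int], ...]
    planted: tuple[PlantedPattern, ...] = ()
    scaffold_mix: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for _, size in self.classes) != self.n_compounds:
            raise FixtureError("class sizes must sum to n_compounds")
        for p in self.planted:
            if not 0.0 <= p.frequency <= 1.0:
                raise FixtureError(f"frequency {p.frequency} outside [0, 1]")
        if sum(self.scaffold_mix.values()) > self.n_compounds:
            raise FixtureError("scaffold_mix exceeds n_compounds")


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetTotalNumHs() > 0]


def _attach(base: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments with a single bond at random free-valence atoms."""
    sites_a, sites_b = _free_valence_atoms(base), _free_valence_atoms(frag)
    if not sites_a or not sites_b:
        return None
    a = int(rng.choice(sites_a))
    b = int(rng.choice(sites_b))
    combo = Chem.RWMol(Chem.CombineMols(base, frag))
    combo.AddBond(a, base.GetNumAtoms() + b, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _parse_fragment(smiles: str) -> Chem.Mol:
    # planted patterns may carry defined [H]; as building material those
    # hydrogens are ordinary, so parse with the default (implicit-H) reader
    mol = Chem.MolFromSmiles(smiles.replace("[H]", ""))
    if mol is None:
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FixtureError(f"cannot parse fragment SMILES {smiles!r}")
    return mol


def _build_molecule(
    planted_frags: Sequence[Chem.Mol],
    scaffold_smiles: str | None,
    must_match: Sequence[PatternQuery],
    must_not_match: Sequence[PatternQuery],
    rng: np.random.Generator,
) -> Chem.Mol:
    for _ in range(_MAX_RETRIES):
        if scaffold_smiles is not None:
            mol = Chem.MolFromSmiles(scaffold_smiles)
        else:
            mol = Chem.MolFromSmiles(str(rng.choice(DECORATIONS)))
        ok = True
        for frag in planted_frags:
            mol2 = _attach(mol, frag, rng)
            if mol2 is None:
                ok = False
                break
            mol = mol2
        if not ok:
            continue
        n_extra = int(rng.integers(1, 3))
        for _ in range(n_extra):
            frag = Chem.MolFromSmiles(str(rng.choice(DECORATIONS)))
            mol2 = _attach(mol, frag, rng)
            if mol2 is not None:
                mol = mol2
        if all(matches(q, mol) for q in must_match) and not any(
            matches(q, mol) for q in must_not_match
        ):
            return mol
    raise FixtureError(
        "exhausted redraw budget; planted patterns collide with the decoration pool"
    )


def generate_compound_set(
    spec: FixtureSpec,
) -> tuple[list[CompoundRecord], "np.ndarray", list[str]]:
    """Generate records plus the exact ground-truth occurrence table.

    Returns ``(records, truth, pattern_ids)`` where ``truth[i, j]`` says
    whether planted pattern j was attached to compound i. Every planted
    pattern occurs in exactly ``round(freq * n_eligible_pool ... )`` —
    precisely ``round(frequency * n_compounds)`` compounds (drawn from the
    restricted classes when given), and in no others; verified with the
    real matcher at build time.
    """
    rng = np.random.default_rng(spec.seed)
    class_of_index: list[str] = []
    for name, size in spec.classes:
        class_of_index.extend([name] * size)

    queries = [compile_smiles(f"P{j:03d}", p.smiles) for j, p in enumerate(spec.planted)]
    frags = [_parse_fragment(p.smiles) for p in spec.planted]

    n = spec.n_compounds
    truth = np.zeros((n, len(spec.planted)), dtype=bool)
    for j, p in enumerate(spec.planted):
        eligible = [
            i
            for i in range(n)
            if p.restrict_to_classes is None or class_of_index[i] in p.restrict_to_classes
        ]
        n_target = int(round(p.frequency * n))
        if n_target > len(eligible):
            raise FixtureError(
                f"pattern {p.smiles!r}: {n_target} plantings requested but only "
                f"{len(eligible)} eligible compounds"
            )
        chosen = rng.choice(len(eligible), size=n_target, replace=False)
        for c in chosen:
            truth[eligible[int(c)], j] = True

    scaffold_of_index: dict[int, str] = {}
    cursor = 0
    for name, count in sorted(spec.scaffold_mix.items()):
        for _ in range(count):
            scaffold_of_index[cursor] = name
            cursor += 1
    scaffold_smiles = dict(BASIC_SCAFFOLDS)

    records: list[CompoundRecord] = []
    for i in range(n):
        planted_here = [frags[j] for j in range(len(frags)) if truth[i, j]]
        must = [queries[j] for j in range(len(queries)) if truth[i, j]]
        must_not = [queries[j] for j in range(len(queries)) if not truth[i, j]]
        core = scaffold_smiles.get(scaffold_of_index.get(i, ""), None)
        mol = _build_molecule(planted_here, core, must, must_not, rng)
        records.append(
            CompoundRecord(
                compound_id=f"FIX_{i + 1:04d}",
                smiles=canonical_smiles(mol),
                mol=mol,
                chem_class=class_of_index[i],
            )
        )
    return records, truth, [q.substructure_id for q in queries]


def demo_catalog(spec: FixtureSpec) -> list[SubstructureRecord]:
    """Catalog rows for the planted patterns, in catalog-file schema."""
    return [
        SubstructureRecord(f"P{j:03d}", f"planted-{j}", p.smiles)
        for j, p in enumerate(spec.planted)
    ]


def generate_library(
    scaffold_mix: dict[str, int],
    n_decoys: int = 0,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Screening library: decorated scaffold carriers plus scaffold-free
    decoys, deterministic per seed. Each molecule is verified to carry (or
    not carry) its intended scaffold."""
    rng = np.random.default_rng(seed)
    scaffold_smiles = dict(BASIC_SCAFFOLDS)
    scaffold_queries = {name: compile_smiles(name, smi) for name, smi in BASIC_SCAFFOLDS}
    records: list[CompoundRecord] = []
    idx = 0
    for name, count in sorted(scaffold_mix.items()):
        if name not in scaffold_smiles:
            raise FixtureError(f"unknown scaffold {name!r}")
        for _ in range(count):
            mol = _build_molecule(
                [], scaffold_smiles[name], [scaffold_queries[name]], [], rng
            )
            idx += 1
            records.append(
                CompoundRecord(f"LIB_{idx:05d}", canonical_smiles(mol), mol, chem_class=name)
            )
    all_queries = list(scaffold_queries.values())
    for _ in range(n_decoys):
        mol = _build_molecule([], None, [], all_queries, rng)
        idx += 1
        records.append(CompoundRecord(f"LIB_{idx:05d}", canonical_smiles(mol), mol, chem_class="decoy"))
    return records


def demo_spec(seed: int = 0) -> FixtureSpec:
    """A study-shaped demo: 174 compounds in 18 unequal classes (the largest
    holding 70 and 31 members), several planted patterns at controlled
    frequencies, and scaffold carriers for all five basic cores."""
    other = [(f"minor_{i:02d}", 2 if i < 4 else 1) for i in range(11)]  # 15 compounds
    classes = (
        ("flavonoid", 70),
        ("verapamil_analog", 31),
        ("gsh_analog", 18),
        ("xanthone", 18),
        ("phenothiazine", 12),
        ("pyrrolopyrimidine", 6),
        ("purine", 4),
        *other,
    )
    # patterns chosen mutually non-nested and absent from the scaffold cores,
    # so the planted truth is exactly recoverable
    planted = (
        PlantedPattern("NC(=O)C", 0.50),
        PlantedPattern("Clc1ccccc1", 0.20),
        PlantedPattern("Oc1ccc([H])cc1", 0.30, restrict_to_classes=("flavonoid",)),
        PlantedPattern("CNC", 0.10, restrict_to_classes=("verapamil_analog",)),
        PlantedPattern("OCCO", 0.05, restrict_to_classes=("gsh_analog",)),
    )
    scaffold_mix = {
        "chromone": 40,
        "xanthone": 18,
        "phenothiazine": 12,
        "purine": 20,
        "9-deazapurine": 9,
    }
    return FixtureSpec(
        n_compounds=174,
        classes=classes,
        planted=planted,
        scaffold_mix=scaffold_mix,
        seed=seed,
    )
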