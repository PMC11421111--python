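"""Scaffold-filtered virtual screening against a signature.

The library is first downsized to compounds carrying at least one basic
scaffold. Each survivor is then scored as the sum of signature totals over
the distinct substructures it contains, restricted to the primary tier, the
secondary tier, or both ("combined"). One ranked list is produced per
(scaffold × selection); a compound carrying two scaffolds appears in both
lists. A property-balanced shortlist helper picks top scorers round-robin
over a CLogP × MW grid, standing in for the human review step only insofar
as it exports a balanced candidate table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from rdkit import Chem

from .chem_io import CompoundRecord, ScaffoldDef
from .descriptors import DESCRIPTOR_PROVIDER, compute_properties
from .pattern_engine import PatternQuery, compile_scaffolds, compile_smiles, matches
from .signature import SignatureEntry

Selection = Literal["primary", "secondary", "combined"]
SELECTIONS: tuple[Selection, ...] = ("primary", "secondary", "combined")


@dataclass
class ScreeningHit:
    """A library compound that survived the scaffold filter."""

    compound_id: str
    smiles: str
    scaffolds: set[str]
    matched_primary: set[str] = field(default_factory=set)
    matched_secondary: set[str] = field(default_factory=set)
    score_primary: int = 0
    score_secondary: int = 0
    mw: float = 0.0

    @property
    def score_combined(self) -> int:
        return self.score_primary + self.score_secondary


@dataclass
class RankedEntry:
    """One row of a ranked list: a hit with the selection's score attached."""

    compound_id: str
    smiles: str
    scaffolds: set[str]
    matched_primary: set[str]
    matched_secondary: set[str]
    score: int


@dataclass
class ScaffoldFilterResult:
    hits: list[tuple[CompoundRecord, set[str]]]
    per_scaffold_counts: dict[str, int]
    n_multi_scaffold: int
    n_screened: int


def filter_by_scaffolds(
    library: Iterable[CompoundRecord], scaffolds: Sequence[ScaffoldDef]
) -> ScaffoldFilterResult:
    """Single-pass scaffold filter: keep compounds matching >= 1 scaffold.

    Reports per-scaffold hit counts and how many compounds carried more than
    one scaffold. Streaming-safe: the library may be a generator.
    """
    compiled = compile_scaffolds(scaffolds)
    counts = {q.substructure_id: 0 for q in compiled}
    hits: list[tuple[CompoundRecord, set[str]]] = []
    n_multi = 0
    n_screened = 0
    for rec in library:
        n_screened += 1
        found = {q.substructure_id for q in compiled if matches(q, rec.mol)}
        if not found:
            continue
        for name in found:
            counts[name] += 1
        if len(found) > 1:
            n_multi += 1
        hits.append((rec, found))
    return ScaffoldFilterResult(hits, counts, n_multi, n_screened)


class SignatureScorer:
    """Compiled signature: patterns plus their totals and tiers."""

    def __init__(self, entries: Sequence[SignatureEntry], smiles_of: Mapping[str, str] | None = None):
        self.entries = list(entries)
        self.totals = {e.substructure_id: e.total for e in self.entries}
        self.tiers = {e.substructure_id: e.tier for e in self.entries}
        self.queries: list[PatternQuery] = []
        for e in self.entries:
            smi = e.smiles or (smiles_of or {}).get(e.substructure_id)
            if not smi:
                raise ValueError(f"no SMILES available for {e.substructure_id!r}")
            self.queries.append(compile_smiles(e.substructure_id, smi))

    def matched(self, mol: Chem.Mol) -> tuple[set[str], set[str]]:
        prim: set[str] = set()
        sec: set[str] = set()
        for q in self.queries:
            if matches(q, mol):
                (prim if self.tiers[q.substructure_id] == "primary" else sec).add(q.substructure_id)
        return prim, sec

    def score(self, mol: Chem.Mol, selection: Selection) -> tuple[int, set[str], set[str]]:
        prim, sec = self.matched(mol)
        chosen: set[str] = set()
        if selection in ("primary", "combined"):
            chosen |= prim
        if selection in ("secondary", "combined"):
            chosen |= sec
        return sum(self.totals[s] for s in chosen), prim, sec


def score_compound(
    mol: Chem.Mol, signature: Sequence[SignatureEntry] | SignatureScorer, selection: Selection
) -> tuple[int, set[str], set[str]]:
    """Score = sum of signature totals over distinct matched substructures in
    the selected tier(s); multiplicity is ignored."""
    scorer = signature if isinstance(signature, SignatureScorer) else SignatureScorer(signature)
    return scorer.score(mol, selection)


def score_hits(
    filtered: ScaffoldFilterResult, scorer: SignatureScorer
) -> list[ScreeningHit]:
    """Turn the scaffold-filter survivors into fully scored hits."""
    out: list[ScreeningHit] = []
    for rec, scaffold_names in filtered.hits:
        prim, sec = scorer.matched(rec.mol)
        out.append(
            ScreeningHit(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                scaffolds=scaffold_names,
                matched_primary=prim,
                matched_secondary=sec,
                score_primary=sum(scorer.totals[s] for s in prim),
                score_secondary=sum(scorer.totals[s] for s in sec),
                mw=compute_properties(rec.mol).mw,
            )
        )
    return out


def _selection_score(hit: ScreeningHit, selection: Selection) -> int:
    return {
        "primary": hit.score_primary,
        "secondary": hit.score_secondary,
        "combined": hit.score_combined,
    }[selection]


def _rank_key(hit: ScreeningHit, selection: Selection):
    # score desc, more matched primaries, lower MW, then id — a total order
    return (
        -_selection_score(hit, selection),
        -len(hit.matched_primary),
        hit.mw,
        hit.compound_id,
    )


def generate_ranked_lists(
    hits: Sequence[ScreeningHit],
    selections: Sequence[Selection] = SELECTIONS,
    per_scaffold: bool = True,
) -> dict[tuple[str, str], list[RankedEntry]]:
    """One deterministic ranked list per (scaffold × selection).

    With ``per_scaffold=False`` a single pooled list per selection is
    produced under the scaffold key ``"all"``. Input order never affects the
    output ordering.
    """
    scaffold_keys = sorted({s for h in hits for s in h.scaffolds}) if per_scaffold else ["all"]
    lists: dict[tuple[str, str], list[RankedEntry]] = {}
    for scaffold in scaffold_keys:
        members = [h for h in hits if per_scaffold and scaffold in h.scaffolds or not per_scaffold]
        for selection in selections:
            ordered = sorted(members, key=lambda h: _rank_key(h, selection))
            lists[(scaffold, selection)] = [
                RankedEntry(
                    h.compound_id,
                    h.smiles,
                    set(h.scaffolds),
                    set(h.matched_primary),
                    set(h.matched_secondary),
                    _selection_score(h, selection),
                )
                for h in ordered
            ]
    return lists


def shortlist_balanced(
    candidates: Sequence[ScreeningHit],
    k: int,
    clogp_bins: Sequence[float] = (0.0, 2.0, 4.0),
    mw_bins: Sequence[float] = (300.0, 400.0, 500.0),
    selection: Selection = "combined",
) -> list[ScreeningHit]:
    """Property-balanced top-scorer shortlist.

    Candidates are placed on the 2D grid defined by the CLogP and MW bin
    edges; cells are visited round-robin (in fixed grid order) taking the
    highest-scoring unused candidate per occupied cell until ``k`` picks are
    made. Deterministic for fixed inputs.
    """
    import bisect

    def cell(hit: ScreeningHit) -> tuple[int, int]:
        props = compute_properties(Chem.MolFromSmiles(hit.smiles))
        return (
            bisect.bisect_right(list(clogp_bins), props.clogp),
            bisect.bisect_right(list(mw_bins), props.mw),
        )

    grid: dict[tuple[int, int], list[ScreeningHit]] = {}
    for hit in candidates:
        grid.setdefault(cell(hit), []).append(hit)
    for members in grid.values():
        members.sort(key=lambda h: _rank_key(h, selection))
    chosen: list[ScreeningHit] = []
    occupied = sorted(grid)
    while len(chosen) < k and any(grid[c] for c in occupied):
        for c in occupied:
            if len(chosen) >= k:
                break
            if grid[c]:
                chosen.append(grid[c].pop(0))
    return chosen


def write_manifest(
    path: str | Path,
    config: Mapping,
    counts: Mapping[str, int],
    seed: int | None = None,
) -> None:
    """JSON run manifest: config, counts, seed and descriptor provenance."""
    payload = {
        "config": dict(config),
        "counts": dict(counts),
        "seed": seed,
        "descriptor_provider": DESCRIPTOR_PROVIDER,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
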