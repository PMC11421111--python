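"""Readers and writers for compound tables, substructure catalogs, scaffold
definitions, screening libraries and ranked output lists.

All tabular I/O is UTF-8 CSV/TSV (delimiter auto-detected from the extension
or sniffed, overridable). SDF and one-SMILES-per-line files are accepted for
screening libraries. Invalid rows are skipped with a per-row rejection report
by default; ``strict=True`` turns the first rejection into an error.

SMILES are canonicalized (RDKit) for storage and round-tripping; substructure
matching downstream always works on the parsed molecule, never the string.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class DataError(Exception):
    """A problem with the input data (exit code 1 in the CLI)."""


class ConfigError(Exception):
    """A problem with configuration / file schema (exit code 2 in the CLI)."""


class DuplicateIdError(DataError):
    pass


class EmptyDatasetError(DataError):
    pass


@dataclass(frozen=True)
class Rejection:
    """One skipped input row: 1-based data-row number and the reason."""

    row: int
    identifier: str | None
    reason: str


@dataclass
class CompoundRecord:
    """One molecule of a dataset or screening library.

    ``bioactivity_span`` is the (low, high) concentration window in µM in
    which the annotated effect was observed, when reported. ``extra`` carries
    passthrough columns (PubChem CID, ChEMBL ID, CAS, ...) untouched.
    """

    compound_id: str
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    name: str | None = None
    chem_class: str | None = None
    bioactivity_span: tuple[float, float] | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class SubstructureRecord:
    """One catalog entry: a pattern SMILES possibly containing defined ``[H]``."""

    substructure_id: str
    name: str
    smiles: str


@dataclass
class ScaffoldDef:
    """A named basic-scaffold core (chromone, xanthone, phenothiazine, ...)."""

    scaffold_name: str
    smiles: str


#: default column resolution for compound tables
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "id",
    "smiles": "smiles",
    "name": "name",
    "class": "class",
    "activity_low_uM": "activity_low_uM",
    "activity_high_uM": "activity_high_uM",
}

_KNOWN_KEYS = set(DEFAULT_COLUMN_MAP)


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    sample = path.read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _parse_mol(smiles: str) -> Chem.Mol | None:
    if not smiles or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles.strip())


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _read_rows(path: str | Path, delimiter: str | None) -> tuple[list[str], list[dict[str, str]]]:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"input file not found: {p}")
    delim = _sniff_delimiter(p, delimiter)
    with p.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ConfigError(f"empty file: {p}")
        return list(reader.fieldnames), list(reader)


def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    strict: bool = False,
    require_class: bool = False,
) -> tuple[list[CompoundRecord], list[Rejection]]:
    """Read a compound table (CSV/TSV) into records plus a rejection report.

    ``column_map`` maps the logical keys ``id, smiles, name, class,
    activity_low_uM, activity_high_uM`` to the file's column names; unmapped
    file columns are kept verbatim in ``record.extra``. Rows whose SMILES do
    not parse are rejected with their 1-based data-row number; duplicated ids
    raise :class:`DuplicateIdError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    fieldnames, rows = _read_rows(path, delimiter)
    for key in ("id", "smiles"):
        if cmap[key] not in fieldnames:
            raise ConfigError(f"required column {cmap[key]!r} (for {key!r}) missing in {path}")
    mapped_cols = {cmap[k] for k in _KNOWN_KEYS if cmap[k] in fieldnames}

    records: list[CompoundRecord] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        cid = (row.get(cmap["id"]) or "").strip()
        smiles = (row.get(cmap["smiles"]) or "").strip()
        if not cid:
            rejections.append(Rejection(i, None, "missing compound id"))
            continue
        if cid in seen:
            raise DuplicateIdError(f"duplicate compound id {cid!r} at row {i}")
        mol = _parse_mol(smiles)
        if mol is None:
            rejections.append(Rejection(i, cid, f"unparseable SMILES {smiles!r}"))
            continue
        chem_class = (row.get(cmap["class"]) or "").strip() or None
        if require_class and chem_class is None:
            rejections.append(Rejection(i, cid, "missing class label"))
            continue
        span = None
        lo, hi = (row.get(cmap["activity_low_uM"]) or "").strip(), (
            row.get(cmap["activity_high_uM"]) or ""
        ).strip()
        if lo or hi:
            try:
                span = (float(lo or hi), float(hi or lo))
            except ValueError:
                rejections.append(Rejection(i, cid, f"bad activity span {lo!r}/{hi!r}"))
                continue
        extra = {k: v for k, v in row.items() if k not in mapped_cols and k is not None}
        seen.add(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=canonical_smiles(mol),
                mol=mol,
                name=(row.get(cmap["name"]) or "").strip() or None,
                chem_class=chem_class,
                bioactivity_span=span,
                extra=extra,
            )
        )
    if strict and rejections:
        r = rejections[0]
        raise DataError(f"row {r.row}: {r.reason}")
    if not records:
        raise EmptyDatasetError(f"no valid compound records in {path}")
    return records, rejections


def read_substructure_catalog(
    path: str | Path,
    delimiter: str | None = None,
    strict: bool = False,
) -> tuple[list[SubstructureRecord], list[Rejection]]:
    """Read a substructure catalog (columns substructure_id, name, smiles).

    Each SMILES must compile to a pattern query; defined ``[H]`` atoms are
    preserved, never folded into implicit hydrogens. Rows that fail to
    compile are rejected with a reason.
    """
    from . import pattern_engine  # local import: avoids a module cycle

    fieldnames, rows = _read_rows(path, delimiter)
    for col in ("substructure_id", "smiles"):
        if col not in fieldnames:
            raise ConfigError(f"required column {col!r} missing in {path}")
    records: list[SubstructureRecord] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        sid = (row.get("substructure_id") or "").strip()
        smiles = (row.get("smiles") or "").strip()
        if not sid:
            rejections.append(Rejection(i, None, "missing substructure id"))
            continue
        if sid in seen:
            raise DuplicateIdError(f"duplicate substructure id {sid!r} at row {i}")
        rec = SubstructureRecord(sid, (row.get("name") or "").strip(), smiles)
        try:
            pattern_engine.compile_pattern(rec)
        except pattern_engine.PatternCompileError as exc:
            rejections.append(Rejection(i, sid, str(exc)))
            continue
        seen.add(sid)
        records.append(rec)
    if strict and rejections:
        r = rejections[0]
        raise DataError(f"row {r.row}: {r.reason}")
    if not records:
        raise EmptyDatasetError(f"no valid substructure records in {path}")
    return records, rejections


def read_scaffolds(path: str | Path, delimiter: str | None = None) -> list[ScaffoldDef]:
    """Read a two-column scaffold definition file (scaffold_name, smiles)."""
    fieldnames, rows = _read_rows(path, delimiter)
    for col in ("scaffold_name", "smiles"):
        if col not in fieldnames:
            raise ConfigError(f"required column {col!r} missing in {path}")
    out: list[ScaffoldDef] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        name = (row.get("scaffold_name") or "").strip()
        smiles = (row.get("smiles") or "").strip()
        if name in seen:
            raise DuplicateIdError(f"duplicate scaffold name {name!r} at row {i}")
        if _parse_mol(smiles) is None:
            raise DataError(f"row {i}: unparseable scaffold SMILES {smiles!r}")
        seen.add(name)
        out.append(ScaffoldDef(name, smiles))
    if not out:
        raise EmptyDatasetError(f"no scaffolds in {path}")
    return out


def iter_library(path: str | Path, delimiter: str | None = None) -> Iterator[CompoundRecord]:
    """Stream a screening library from .smi (one SMILES per line, optional id),
    SDF, or a CSV/TSV compound table. Unparseable entries are skipped."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in {".smi", ".smiles", ".txt"}:
        with p.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                mol = _parse_mol(parts[0])
                if mol is None:
                    continue
                cid = parts[1] if len(parts) > 1 else f"LIB_{i:06d}"
                yield CompoundRecord(cid, canonical_smiles(mol), mol)
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(p))
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"LIB_{i:06d}"
            yield CompoundRecord(cid, canonical_smiles(mol), mol)
    else:
        records, _ = read_compound_table(p, delimiter=delimiter)
        yield from records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records back to CSV preserving id, canonical SMILES and labels."""
    p = Path(path)
    with p.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "name", "class", "activity_low_uM", "activity_high_uM"])
        for r in records:
            lo, hi = ("", "") if r.bioactivity_span is None else r.bioactivity_span
            writer.writerow([r.compound_id, r.smiles, r.name or "", r.chem_class or "", lo, hi])


RANKED_LIST_COLUMNS = [
    "compound_id",
    "smiles",
    "scaffolds",
    "score",
    "n_matched_primary",
    "n_matched_secondary",
    "rank",
]


def write_ranked_list(hits: Sequence, path: str | Path) -> None:
    """Write an ordered hit list as CSV; rank is the 1-based list position."""
    p = Path(path)
    with p.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RANKED_LIST_COLUMNS)
        for rank, h in enumerate(hits, start=1):
            writer.writerow(
                [
                    h.compound_id,
                    h.smiles,
                    ";".join(sorted(h.scaffolds)),
                    h.score,
                    len(h.matched_primary),
                    len(h.matched_secondary),
                    rank,
                ]
            )


def read_ranked_list(path: str | Path) -> list[dict[str, str]]:
    """Round-trip reader for :func:`write_ranked_list` output."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
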