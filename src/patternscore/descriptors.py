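"""Per-compound physicochemical / molecular-structural properties and
dataset-level validation summaries.

Properties: CLogP (Crippen), MW (g/mol, standard atomic masses), MR (Crippen
molar refractivity), TPSA (Å²), H-bond donor/acceptor counts, rotatable
bonds, heavy atoms. CLogS is optional and not provided by the rdkit
provider. MW and the integer counts are implementation-independent; CLogP
and MR are definition-dependent, so every output carries a
``descriptor_provider`` tag.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

DESCRIPTOR_PROVIDER = f"rdkit-{rdkit.__version__}"

PROPERTY_NAMES = ("clogp", "mw", "mr", "tpsa", "n_hbd", "n_hba", "n_rotb", "n_heavy")


@dataclass(frozen=True)
class PropertySet:
    clogp: float
    mw: float
    tpsa: float
    mr: float
    n_hbd: int
    n_hba: int
    n_rotb: int
    n_heavy: int
    clogs: float | None = None


def compute_properties(mol: Chem.Mol) -> PropertySet:
    """Deterministic property set for one molecule, computed from the
    structure as given (no charge/tautomer normalization)."""
    return PropertySet(
        clogp=Crippen.MolLogP(mol),
        mw=Descriptors.MolWt(mol),
        mr=Crippen.MolMR(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        n_hbd=Lipinski.NumHDonors(mol),
        n_hba=Lipinski.NumHAcceptors(mol),
        n_rotb=Lipinski.NumRotatableBonds(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
    )


def properties_frame(records: Sequence) -> pd.DataFrame:
    """Property table (one row per compound, indexed by compound_id)."""
    rows = {}
    for rec in records:
        props = asdict(compute_properties(rec.mol))
        props.pop("clogs")
        rows[rec.compound_id] = props
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "compound_id"
    return frame[list(PROPERTY_NAMES)]


@dataclass
class DatasetSummary:
    """Median/mean per property plus histograms over the accepted records."""

    n: int
    median: dict[str, float]
    mean: dict[str, float]
    histograms: dict[str, tuple[list[float], list[int]]]  # property -> (edges, counts)
    descriptor_provider: str = DESCRIPTOR_PROVIDER
    median_convention: str = "mean-of-middle-two"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.median, "mean": self.mean})


def _median(values: np.ndarray, convention: Literal["mean-of-middle-two", "lower"]) -> float:
    if convention == "mean-of-middle-two":
        return float(np.median(values))
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def summarize_dataset(
    records: Sequence,
    bins: int = 20,
    median_convention: Literal["mean-of-middle-two", "lower"] = "mean-of-middle-two",
) -> DatasetSummary:
    """Table-style validation summary (median and mean per property) plus
    per-property histograms whose counts sum to n."""
    frame = properties_frame(records)
    median: dict[str, float] = {}
    mean: dict[str, float] = {}
    histograms: dict[str, tuple[list[float], list[int]]] = {}
    for prop in PROPERTY_NAMES:
        values = frame[prop].to_numpy(dtype=float)
        median[prop] = _median(values, median_convention)
        mean[prop] = float(values.mean())
        counts, edges = np.histogram(values, bins=bins)
        histograms[prop] = (edges.tolist(), counts.tolist())
    return DatasetSummary(
        n=len(frame),
        median=median,
        mean=mean,
        histograms=histograms,
        median_convention=median_convention,
    )


def class_composition(records: Iterable) -> pd.Series:
    """Fraction of the dataset per chemical class, descending.

    Multiply by 100 for the percentage view used in dataset validation
    reports (e.g. the share of the largest class).
    """
    labels = [r.chem_class if r.chem_class is not None else "<unlabeled>" for r in records]
    counts = pd.Series(labels, dtype="object").value_counts()
    return counts / counts.sum()
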