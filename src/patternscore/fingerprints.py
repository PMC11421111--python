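"""The four occurrence/flexibility fingerprints.

Per substructure:

* ``f1`` — fraction of compounds containing it (fingerprint I);
* ``f2`` — fraction of chemical classes with at least one matching member
  (fingerprint II);
* ``q3 = f1 / flexibility`` and ``q4 = f2 / flexibility`` (fingerprints
  III/IV), where flexibility is the pattern's substitutable-H count per
  heavy atom. Dividing by flexibility rewards structurally specific
  patterns that cannot compete on raw occurrence with very general ones.

Fractions are stored on the 0–1 scale internally; formatting to percent
happens only at I/O. A flexibility of 0 (fully hydrogen-defined pattern)
makes q3/q4 undefined — represented as NaN, handled downstream by the
signature's gap-fill path rather than as +inf.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pattern_engine import OccurrenceMatrix, PatternQuery


class MissingClassError(Exception):
    """Raised when compounds lack the class label fingerprint II requires."""

    def __init__(self, compound_ids: Sequence[str]):
        self.compound_ids = list(compound_ids)
        super().__init__(f"compounds without class label: {', '.join(self.compound_ids)}")


FINGERPRINT_COLUMNS = ["n_hits", "f1", "n_class_hits", "f2", "flexibility", "q3", "q4"]


def fraction_occurrence(matrix: OccurrenceMatrix) -> pd.Series:
    """Fingerprint I: column sum / number of compounds."""
    if len(matrix.compound_ids) == 0:
        raise ValueError("occurrence matrix has no compounds")
    frame = matrix.to_frame()
    return frame.sum(axis=0) / len(frame)


def class_occurrence(matrix: OccurrenceMatrix, class_of: Mapping[str, str]) -> pd.Series:
    """Fingerprint II: fraction of classes with >= 1 matching member."""
    missing = [cid for cid in matrix.compound_ids if class_of.get(cid) in (None, "")]
    if missing:
        raise MissingClassError(missing)
    frame = matrix.to_frame()
    classes = pd.Series({cid: class_of[cid] for cid in matrix.compound_ids})
    n_classes = classes.nunique()
    per_class = frame.groupby(classes).any()  # class x substructure
    return per_class.sum(axis=0) / n_classes


def flexibility_quotients(
    f1: pd.Series, f2: pd.Series, patterns: Sequence[PatternQuery]
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Fingerprints III/IV: divide f1/f2 by each pattern's flexibility.

    Returns (flexibility, q3, q4); quotients are NaN where flexibility is 0.
    """
    flex = pd.Series({p.substructure_id: p.flexibility for p in patterns})
    flex = flex.reindex(f1.index)
    denom = flex.replace(0.0, np.nan)
    return flex, f1 / denom, f2 / denom


def build_fingerprint_table(
    matrix: OccurrenceMatrix,
    class_of: Mapping[str, str],
    patterns: Sequence[PatternQuery],
) -> pd.DataFrame:
    """Full fingerprint table indexed by substructure_id.

    Columns: raw hit counts, f1, class hit counts, f2, flexibility, q3, q4 —
    the per-substructure quantities the signature is scored from.
    """
    f1 = fraction_occurrence(matrix)
    f2 = class_occurrence(matrix, class_of)
    flex, q3, q4 = flexibility_quotients(f1, f2, patterns)
    frame = matrix.to_frame()
    classes = pd.Series({cid: class_of[cid] for cid in matrix.compound_ids})
    table = pd.DataFrame(
        {
            "n_hits": frame.sum(axis=0).astype(int),
            "f1": f1,
            "n_class_hits": frame.groupby(classes).any().sum(axis=0).astype(int),
            "f2": f2,
            "flexibility": flex,
            "q3": q3,
            "q4": q4,
        }
    )
    table.index.name = "substructure_id"
    return table[FINGERPRINT_COLUMNS]
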