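"""Score binning, thresholding/gap-filling, tier classification, and the
ranked signature table.

Each of the four fingerprint values is mapped onto an integer score 0–10 via
fixed bin edges (lower-inclusive / upper-exclusive, top bin open above):

    >= 0.90 -> 10, [0.80, 0.90) -> 9, ..., [0.10, 0.20) -> 2,
    [0.01, 0.10) -> 1, < 0.01 -> 0.

Fingerprint I/II scores are zeroed unless the substructure is present in at
least 20% of compounds (score >= 3), EXCEPT when the corresponding
flexibility-quotient fingerprint (III for I, IV for II) scores 3 or more:
then the zeroed raw score of 1 or 2 is restored ("gap-filling"), which keeps
structurally specific but rare substructures in play. Fingerprint III/IV
scores are never thresholded.

A substructure is a *primary positive* if (i) it occurs in >= 20% of
compounds or classes, or (ii) its flexibility quotient (III and/or IV)
reaches 0.2 while its occurrence (I and/or II) reaches 10%. Everything else
is *secondary positive*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pattern_engine import PatternQuery

#: bin edges: score = number of edges <= value (so >= 0.90 -> 10)
BIN_EDGES: tuple[float, ...] = (0.01, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

#: fingerprint I/II are considered only at >= 20% presence (score 3)
PRESENCE_THRESHOLD = 0.20
#: primary criterion (ii): occurrence in I and/or II by >= 10% ...
OCCURRENCE_THRESHOLD = 0.10
#: ... combined with a flexibility quotient (III and/or IV) of >= 0.2
QUOTIENT_THRESHOLD = 0.20


def bin_score(value: float, edges: Sequence[float] = BIN_EDGES) -> int:
    """Map a fingerprint value to its 0-10 score.

    Bins are lower-inclusive/upper-exclusive and tile [0, inf) without gaps;
    the top bin is unbounded above. Monotone non-decreasing in ``value``.
    """
    if value < 0 or math.isnan(value):
        raise ValueError(f"fingerprint value must be >= 0, got {value}")
    return int(np.searchsorted(np.asarray(edges), value, side="right"))


def threshold_and_fill(
    raw: tuple[int, int, int, int],
    f1: float,
    f2: float,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> tuple[int, int, int, int]:
    """Apply the 20% presence threshold to s1/s2 with the gap-filling rule.

    ``raw`` holds the unthresholded bin scores (s1, s2, s3, s4). s1 is
    zeroed when f1 < threshold, but a zeroed raw score of 1 or 2 is restored
    when s3 >= 3; symmetrically s2 with f2 and s4. s3/s4 pass through.
    """
    s1_raw, s2_raw, s3, s4 = raw

    def adjust(s_raw: int, f: float, s_quot: int) -> int:
        if f >= presence_threshold:
            return s_raw
        if s_quot >= 3 and s_raw in (1, 2):
            return s_raw  # gap filled from the occurrence fingerprint
        return 0

    return adjust(s1_raw, f1, s3), adjust(s2_raw, f2, s4), s3, s4


def classify_tier(
    f1: float,
    f2: float,
    q3: float,
    q4: float,
    presence_threshold: float = PRESENCE_THRESHOLD,
    occurrence_threshold: float = OCCURRENCE_THRESHOLD,
    quotient_threshold: float = QUOTIENT_THRESHOLD,
) -> str:
    """Primary/secondary tier. NaN quotients (flexibility 0) fail criterion (ii)."""
    occ = max(f1, f2)
    if occ >= presence_threshold:
        return "primary"
    quot = np.nanmax([q3, q4, -np.inf])
    if quot >= quotient_threshold and occ >= occurrence_threshold:
        return "primary"
    return "secondary"


@dataclass
class SignatureEntry:
    substructure_id: str
    name: str
    smiles: str
    f1: float
    f2: float
    flexibility: float
    q3: float
    q4: float
    s1: int
    s2: int
    s3: int
    s4: int
    tier: str

    @property
    def total(self) -> int:
        return self.s1 + self.s2 + self.s3 + self.s4


def score_values(
    f1: float,
    f2: float,
    q3: float,
    q4: float,
    edges: Sequence[float] = BIN_EDGES,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> tuple[int, int, int, int]:
    """Bin all four fingerprint values and apply threshold/gap-fill.

    Undefined quotients (NaN, from flexibility 0) contribute s3/s4 equal to
    the already-thresholded s1/s2, so the mapping stays total.
    """
    s1_raw, s2_raw = bin_score(f1, edges), bin_score(f2, edges)
    s3 = bin_score(q3, edges) if not math.isnan(q3) else None
    s4 = bin_score(q4, edges) if not math.isnan(q4) else None
    s1, s2, _, _ = threshold_and_fill(
        (s1_raw, s2_raw, s3 or 0, s4 or 0), f1, f2, presence_threshold
    )
    if s3 is None:
        s3 = s1
    if s4 is None:
        s4 = s2
    return s1, s2, s3, s4


def build_signature(
    fingerprint_table: pd.DataFrame,
    catalog_meta: Mapping[str, tuple[str, str]] | None = None,
    edges: Sequence[float] = BIN_EDGES,
    presence_threshold: float = PRESENCE_THRESHOLD,
    occurrence_threshold: float = OCCURRENCE_THRESHOLD,
    quotient_threshold: float = QUOTIENT_THRESHOLD,
) -> list[SignatureEntry]:
    """Score every fingerprint row and rank by total score, descending.

    ``catalog_meta`` maps substructure_id -> (name, smiles) for the output
    table. Ties in total score break on higher s1, then higher s3, then
    substructure_id, so the ordering is deterministic.
    """
    entries: list[SignatureEntry] = []
    for sid, row in fingerprint_table.iterrows():
        s1, s2, s3, s4 = score_values(
            row["f1"], row["f2"], row["q3"], row["q4"], edges, presence_threshold
        )
        name, smiles = (catalog_meta or {}).get(sid, ("", ""))
        entries.append(
            SignatureEntry(
                substructure_id=str(sid),
                name=name,
                smiles=smiles,
                f1=float(row["f1"]),
                f2=float(row["f2"]),
                flexibility=float(row["flexibility"]),
                q3=float(row["q3"]),
                q4=float(row["q4"]),
                s1=s1,
                s2=s2,
                s3=s3,
                s4=s4,
                tier=classify_tier(
                    row["f1"],
                    row["f2"],
                    row["q3"],
                    row["q4"],
                    presence_threshold,
                    occurrence_threshold,
                    quotient_threshold,
                ),
            )
        )
    entries.sort(key=lambda e: (-e.total, -e.s1, -e.s3, e.substructure_id))
    return entries


def signature_to_frame(entries: Sequence[SignatureEntry]) -> pd.DataFrame:
    """Flat table of the ranked signature (one row per substructure)."""
    return pd.DataFrame(
        [
            {
                "substructure_id": e.substructure_id,
                "name": e.name,
                "smiles": e.smiles,
                "f1": e.f1,
                "f2": e.f2,
                "flexibility": e.flexibility,
                "q3": e.q3,
                "q4": e.q4,
                "s1": e.s1,
                "s2": e.s2,
                "s3": e.s3,
                "s4": e.s4,
                "total": e.total,
                "tier": e.tier,
            }
            for e in entries
        ]
    )


def tier_counts(entries: Sequence[SignatureEntry]) -> dict[str, int]:
    counts = {"primary": 0, "secondary": 0}
    for e in entries:
        counts[e.tier] += 1
    return counts
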