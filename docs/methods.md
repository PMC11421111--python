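# Methods

## Problem setting

The package targets datasets too small and too redundant for statistical
learning: on the order of 10²–10³ curated literature compounds, unequally
split over a few dozen chemical classes, annotated with a qualitative
effect (the motivating case is ABC-transporter activation, a rarely
reported mode of action). The unit of knowledge is not a fitted model but a
catalog of chemist-drawn substructures whose occurrence statistics across
the dataset are converted into a transferable scoring signature.

## Pattern semantics

Catalog entries are SMILES interpreted directly as substructure queries:

- element, aromatic/aliphatic state, bond order, formal charge and isotope
  must match exactly as written;
- an explicitly written `[H]` is an *irreplaceable* hydrogen: it compiles
  to a minimum-total-hydrogen-count constraint on its heavy atom (one unit
  per written `[H]`), so the position cannot be substituted;
- every unwritten hydrogen is substitutable by any atom;
- stereochemistry is stripped from pattern and target (patterns are 2D);
- multiple embeddings count once — all downstream statistics are
  presence/absence.

Aromaticity is perceived once, by RDKit's default model, identically for
patterns and targets; that single fixed perception is what makes matching
reproducible. RDKit's *default* mol-as-query matching is looser than these
rules (it lets aliphatic atoms match aromatic ones and ignores charge), so
compilation builds explicit per-atom query atoms instead. The test suite
cross-checks the whole matching route against an independent exhaustive
subgraph-monomorphism search (networkx) on a molecule × pattern panel.

Hydrogen accounting per pattern: `n_H_total` counts the hydrogens of the
pattern read as a molecule with standard-valence implicit hydrogens,
`n_H_defined` counts written `[H]`, and

```
flexibility = (n_H_total − n_H_defined) / n_heavy .
```

A consequence of the strict embedding semantics worth noting: in a pattern
such as `Oc1ccc([H])cc1` the defined hydrogen is *positional* — it sits
para to the hydroxyl, so a 4-substituted phenol does not match even though
other ring hydrogens exist.

## Fingerprints and signature

Fingerprint I is the fraction of compounds containing the pattern;
fingerprint II the fraction of classes with at least one matching member
(a class "contains" a pattern iff ≥ 1 member matches — no quorum).
Fingerprints III/IV divide I/II by the flexibility. Fractions are kept on
the 0–1 scale internally; percent formatting happens only at I/O.

Bin edges for the 0–10 scores are `0.01, 0.10, 0.20, …, 0.90`, read
lower-inclusive / upper-exclusive with the top bin open above — the only
reading that tiles [0, ∞) without gaps (the largest quotient observed in
the motivating dataset, 1.77, is an observed maximum, not a cap). The
20% presence threshold on fingerprints I/II and both tier thresholds are
inclusive (`≥`).

Gap-filling pairs III→I and IV→II: a thresholded-to-zero s1 (raw 1 or 2)
is restored iff s3 ≥ 3, and symmetrically s2 with s4. The pairing follows
the construction of the quotients (III is I's quotient); when both
quotients qualify the result is identical, so the rule is idempotent.

Degenerate input: a fully hydrogen-defined pattern has flexibility 0 and
undefined quotients. These are carried as NaN (never +∞), fail tier
criterion (ii), and contribute s3/s4 equal to the thresholded s1/s2 so the
total stays defined. This cannot occur in typical catalogs but the contract
is total.

Ranking ties (equal totals) break on higher s1, then higher s3, then
substructure id — an arbitrary but documented total order; no ordering of
equal-total rows is claimed to be canonical.

## Screening

Scaffold filtering is plain substructure containment of named cores
(built-ins: chromone, xanthone, phenothiazine, purine, 9-deazapurine,
written as Kekulé SMILES and re-perceived by the same aromaticity model).
No Bemis–Murcko reduction: a xanthone correctly reports both the xanthone
and the embedded chromone core, and multi-scaffold molecules appear in
every matching per-scaffold list.

A compound's score is the **sum** of signature totals over its distinct
matched substructures in the selected tier(s). Summation is the minimal
aggregation consistent with "score by positive substructures"; max- or
count-aggregation would discard the signature's magnitudes. Ranked-list
ties break on more matched primary substructures, then lower MW, then
compound id. The balanced shortlist visits the CLogP × MW grid cells in
fixed order, repeatedly taking each occupied cell's best unused candidate —
a deterministic stand-in for the human "balanced selection" step; it
exports candidates, it does not encode judgment.

## Descriptors

CLogP and MR are Crippen's atomic-contribution versions, TPSA the
topological polar surface area, H-bond donors/acceptors and rotatable
bonds Lipinski-style counts; MW uses standard atomic masses. Only MW and
the integer counts are implementation-independent; CLogP/MR scales differ
between descriptor packages, so all outputs carry
`descriptor_provider = "rdkit-<version>"` and no cross-package equality is
promised. No calculated-solubility (CLogS) model ships with the provider;
the field is optional. Median convention is mean-of-middle-two,
configurable to lower-middle.

## Synthetic data

The fixture generator emulates the *shape* of a curated activation dataset:
the shipped demo spec has 174 compounds in 18 unequal classes (70 + 31 in
the two analog-series classes, 15 spread over 11 minor classes), five
planted patterns at frequencies 0.50/0.20/0.30/0.10/0.05 — the rare ones
restricted to single classes, as analog-series chemistry concentrates
patterns — and 99 scaffold carriers across all five cores. Molecules are
assembled from a scaffold core or bland saturated fragment plus 1–2
decorations joined by single bonds at free-valence positions. Planted
patterns are attached to exactly `round(freq · n)` compounds; every
molecule is verified with the production matcher (planted patterns present,
all other planted patterns absent) and redrawn on collision, up to 30
attempts, so the shipped ground truth is exact. The decoration pool is
chosen so that planted patterns cannot arise by accident, and planted
patterns must be mutually non-nested and absent from scaffold cores —
the generator surfaces violations as errors rather than silently shifting
frequencies.

What passing on synthetic data shows: the occurrence, fingerprint, binning,
tiering and ranking arithmetic is exact, and the pipeline is deterministic
end to end. What it does not show: behaviour on real curation noise
(tautomers, charge-state conventions, drawing variants), drug-like
chemistry, or the generalization of any particular signature — those
depend on the curated inputs, not on this code.

## Problem sizes

The shipped test suite and the acceptance script run entirely on generated
data: the study-shaped 174-compound set, n = 100 planted-recovery sets over
five seeds, a 10 × 5 oracle panel, and screening libraries of a few dozen
molecules — sizes chosen so a full run completes in seconds while every
code path (including multi-scaffold and zero-hit branches) is exercised.

## Known limitations

- No tautomer enumeration: a pattern drawn in one tautomer does not match
  another (purine-type cases must be covered by catalog variants).
- Charges must match exactly as written; no pKa or standardization layer.
- Scaffold assignment is non-exclusive by design; an exclusive tally (e.g.
  counting xanthones apart from chromones) is a downstream reporting choice.
- Scoring weights are the signature totals themselves; no evidence weighting
  by class size or bioactivity magnitude is attempted.
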