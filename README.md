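# patternscore

Substructure-pattern scoring for ligand-based virtual screening aimed at
*rare modes of action* — settings where the known actives are few (a couple
of hundred literature compounds), structurally redundant (a handful of
analog series dominate), and annotated only with a qualitative effect such
as transporter activation. Classical QSAR has nothing to fit here;
`patternscore` instead turns a curated compound set plus a catalog of
chemist-drawn substructures into a ranked *signature* of privileged
patterns, and uses that signature to score scaffold-filtered screening
libraries.

Intended users: medicinal/computational chemists curating small
bioactivity-focused datasets and screening commercial libraries against
them.

## The method

Given a dataset of $n$ compounds in $K$ chemical classes and a catalog of
substructures (SMILES, optionally with defined hydrogens `[H]` marking
positions that must stay unsubstituted), four fingerprint values are
computed per substructure $s$:

- **I** — occurrence: $f_1(s)$ = fraction of compounds containing $s$;
- **II** — class occurrence: $f_2(s)$ = fraction of classes with ≥ 1
  member containing $s$ (de-biases the dominant analog series);
- **III** — $q_3(s) = f_1(s)/\phi(s)$ and **IV** — $q_4(s) = f_2(s)/\phi(s)$,
  where $\phi(s)$ = (number of substitutable hydrogens)/(heavy atoms) is
  the pattern's *average flexibility*. Dividing by $\phi$ rewards
  structurally specific patterns that cannot win on raw occurrence.

Each value is binned to a score 0–10 (≥ 0.90 → 10, [0.80, 0.90) → 9, …,
[0.01, 0.10) → 1, < 0.01 → 0). Scores I/II are zeroed below 20% presence,
except that a zeroed score of 1 or 2 is restored when the paired quotient
fingerprint (III for I, IV for II) scores ≥ 3 ("gap-filling"). Substructures
are *primary positive* if occurrence (I and/or II) reaches 20%, or if a
quotient (III and/or IV) reaches 0.2 while occurrence reaches 10%; all
others are *secondary positive*. The signature is the catalog ranked by
total score (0–40).

Screening: a library is downsized to compounds carrying at least one basic
scaffold (built-ins: chromone, xanthone, phenothiazine, purine,
9-deazapurine), each survivor is scored as the sum of signature totals over
its distinct matched substructures (primary / secondary / combined), and one
ranked list is emitted per scaffold × selection, plus a CLogP × MW balanced
shortlist for human review.

## Worked example

Everything runs on synthetic data with known ground truth — no downloads:

```sh
patternscore simulate --out sim --seed 11          # 174 compounds, 18 classes
patternscore signature --dataset sim/dataset.csv --catalog sim/catalog.csv --out sig
```

```
compounds read: 174 (rejected 0); patterns compiled: 5 (rejected 0)
primary=3, secondary=2
```

`sig/signature.csv` (abridged):

| substructure | f1 | f2 | flex | q3 | s1 s2 s3 s4 | total | tier |
|---|---|---|---|---|---|---|---|
| `NC(=O)C` | 0.500 | 0.667 | 1.25 | 0.400 | 6 7 5 6 | 24 | primary |
| `Clc1ccccc1` | 0.201 | 0.611 | 0.71 | 0.282 | 3 7 3 9 | 22 | primary |
| `Oc1ccc([H])cc1` | 0.299 | 0.056 | 0.71 | 0.418 | 3 0 5 1 | 9 | primary |
| `CNC` | 0.098 | 0.056 | 2.33 | 0.042 | 0 0 1 1 | 2 | secondary |
| `OCCO` | 0.052 | 0.056 | 1.50 | 0.034 | 0 0 1 1 | 2 | secondary |

Reading this: the amide was planted into 50% of compounds and across most
classes, so it scores high everywhere. The para-unsubstituted phenol was
planted only into the largest class: its class occurrence (f2 = 1/18)
collapses, but its low flexibility keeps q3 at 0.42 — the specificity
reward — and it stays primary. `CNC` is frequent-ish but highly flexible
(2.33 substitutable H per heavy atom), so its quotients are tiny and it
drops to the secondary tier.

```sh
patternscore screen --dataset sim/dataset.csv --catalog sim/catalog.csv \
    --library sim/library.smi --out screen --shortlist-k 5
# screened 34, kept 24 (4 with two or more scaffolds)
```

which writes one ranked CSV per scaffold × selection
(`ranked_chromone_combined.csv`, …), a balanced shortlist, and a JSON run
manifest. `patternscore validate` prints the Table-style median/mean
property summary, and `patternscore fingerprint` exports the raw
fingerprint table.

## Layout

- `src/patternscore/chem_io.py` — CSV/TSV/SMILES/SDF readers & writers, rejection reports
- `src/patternscore/pattern_engine.py` — query compilation (defined-H semantics), matching, occurrence matrix, scaffold detection
- `src/patternscore/descriptors.py` — physicochemical properties and dataset summaries
- `src/patternscore/fingerprints.py` — fingerprints I–IV
- `src/patternscore/signature.py` — binning, thresholding/gap-fill, tiering, ranking
- `src/patternscore/screening.py` — scaffold filter, scoring, ranked lists, balanced shortlist
- `src/patternscore/fixtures.py` — synthetic datasets/libraries with exact planted ground truth
- `src/patternscore/cli.py` — `patternscore` command

See `docs/methods.md` for modelling assumptions and numerical conventions.
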