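# cellmatch

Find crystal unit-cell matches in a local structure-metadata database.

When a protein crystal is characterized at a synchrotron beamline, its
unit cell and space group are known within minutes — long before any
structure is solved. If a deposited structure already exists with an
equivalent cell, that is worth knowing immediately: the crystal may be a
previously solved protein, or a crystallized impurity (a host-cell
protein that crystallized instead of the intended target). `cellmatch`
answers this by comparing the reduced primitive cell of the query
against a precomputed database of reduced cells for every entry in a
local PDB-like metadata store, and condensing the hit list into
sequence families so each distinct crystal content appears once.

## Method

1. **Reduction.** The query cell `(a, b, c, α, β, γ)` with space group
   `G` is converted to a canonical primitive (P1) cell: the centering of
   `G` (A, B, C, I, F, or the hexagonal rhombohedral setting) is removed
   by the standard conventional→primitive basis transformation, and the
   result is brought to the unique Niggli-reduced form by the
   Křivý–Gruber iteration. Database entries store the same reduction,
   computed at ingest.

2. **Superposition.** Each cell is represented by four points — the
   origin O and the axis endpoints A, B, C of its Cartesian basis. Two
   reduced cells are compared by the least-squares optimal proper
   rotation and translation superposing the two 4-point sets (the
   Kabsch/MATFIT solution), minimized over all six right-handed
   assignments of the candidate's axes. Proteins are enantiomorphic, so
   mirror superpositions are never considered. The score is

   `rmsd = min over 6 permutations of sqrt( Σ_i ‖ R pᵢ + t − qᵢ ‖² / 4 )`

   and a database entry is a hit when `rmsd ≤ cutoff`, where the default
   cutoff is `max(2.5 Å, 0.01 · (max(a,b,c) + min(a,b,c)))` of the query
   cell as supplied.

3. **Family clustering.** All chain sequences of all hits are greedily
   clustered at ≥ 90% identity over the shorter sequence. Each hit's P1
   cell content is then a multiplicity vector: chains per cluster in the
   asymmetric unit × number of primitive symmetry operators of its space
   group. Hits with identical vectors form one *family*, reported
   through the member with the smallest RMSD.

## Worked example

Build a synthetic database (no downloads needed) and query one of its
cells:

```sh
cellmatch make-fixtures --seed 42 --n-background 30 --n-planted 2 \
    --out-tsv demo.tsv --out-manifest demo_manifest.json
cellmatch build-db --tsv demo.tsv --out demo.jsonl
cellmatch query --unit-cell 66.16,99.36,113.97,90.00,105.97,90.00 \
    --space-group 'C 1 2 1' --db demo.jsonl
```

```
Query cell : 66.16 99.36 113.97  90.00 105.97 90.00
Space group: C 1 2 1
P1 cell    : 59.69 59.69 113.97  98.77 98.77 112.68
Cutoff     : 2.50 A
Hits       : 7

Family  Entry    RMSD (A)  Space group  Members  Organism
---------------------------------------------------------
     1  syn0010      0.00  C 1 2 1            6  Synthetica sp. prot006
     2  syn0018      0.04  C 1 2 1            1  Synthetica sp. prot010
```

Reading the output: the C-centered monoclinic query reduces to a
primitive triclinic cell of half the volume (`59.69 59.69 113.97 …`).
Seven database entries superpose within the 2.5 Å default cutoff, but
they collapse to two families: six entries are the same protein in
essentially the same crystal form (the query's own entry at 0.00 Å plus
five redeposited near-copies), while `syn0018` is an *unrelated* protein
that happens to crystallize in an almost identical cell — exactly the
distinction the family clustering is there to make. `--expand-families`
lists every member with its RMSD; `--json` emits the same report
losslessly for pipeline use.

Databases are built from mmCIF headers (`--mmcif`) or the bulk TSV
format, updated incrementally (`update-db`), and pruned (`purge`).

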