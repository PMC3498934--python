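# Methods

## Problem and model

A crystal lattice has infinitely many valid unit-cell descriptions. Two
depositions of the same crystal form may carry different conventional
cells (different centering settings, permuted axes, remixed basis
vectors), so naive comparison of the six cell parameters misses
matches. `cellmatch` therefore compares *canonical primitive cells*:
every (cell, space group) pair — query and database entry alike — is
mapped to the unique Niggli-reduced primitive cell of its lattice, and
similarity is measured geometrically by rigid-body superposition of the
cell's vertex points. Matching is deliberately based on cell geometry
alone, not on structure factors: it is less selective (false positives
from coincidentally similar cells are expected and are handled by the
family-clustering step) but can run the moment a cell is indexed.

## Reduction to the canonical primitive cell

**Centering removal.** Each centering type maps to one fixed
conventional→primitive transformation matrix (rows express primitive
basis vectors in the conventional basis): identity for P and for the
rhombohedral (`:R`) setting, the standard half-sum matrices for A, B,
C, I (|det| = 1/2), F (1/4) and the obverse hexagonal→rhombohedral
matrix for `:H` settings (1/3). The particular matrix choice is
immaterial because the next step canonicalizes the basis. Bare
rhombohedral symbols ("R3") resolve to the hexagonal setting,
following the International Tables default.

**Niggli reduction.** The Křivý–Gruber (1976) iteration on the metric
parameters (A, B, C, ξ, η, ζ) = (a², b², c², 2bc·cosα, 2ac·cosβ,
2ab·cosγ), with the standard eight steps and ε-stabilized comparisons.
Numerical choices:

- ε = 1e-5 × mean of the current (A, B, C), recomputed every pass. The
  scale must track the *current* cell: a lattice handed over in a very
  oblique description starts with huge squared edges, and a fixed
  initial ε would freeze near-degenerate sign decisions differently
  from a well-described start of the same lattice.
- step cap 1000; exceeding it raises an error (pathological input).
- Cells with squared orthogonalization factor v² ≤ 1e-12 are rejected
  as degenerate before any reduction.

The reduced cell satisfies a ≤ b ≤ c and the Niggli angle conditions,
preserves volume to 1e-9 relative, and is invariant under any integer
unimodular re-description of the lattice (property-tested, and
cross-checked against gemmi's independent Gruber implementation).
Angles within ~0.01° of 90° can in principle settle on either side of
the type-I/type-II boundary; the six-permutation superposition step
absorbs such residual flips, so matching is unaffected.

Space-group symbols are resolved through gemmi's International Tables
data, restricted to the 65 Sohncke groups (the only groups enantiopure
protein crystals can adopt), after applying an optional user alias
table for locally curated nonstandard symbols. An absent symbol means
P1. Operator counts (conventional, and primitive = conventional ÷
centering multiplicity) are stored per entry at ingest.

## Superposition score

Cells are compared as the 4-point sets {O, A, B, C} (origin plus axis
endpoints of the Cartesian basis; a along x, b in the xy-plane,
right-handed). The optimal superposition is the Kabsch SVD solution
with centroid translation and determinant-sign correction, so only
proper rotations occur. The candidate cell is tried under all 3! = 6
joint permutations of its (length, opposite-angle) pairs; each permuted
parameter set is re-orthogonalized with the same right-handed
convention, which is what makes all six candidates proper (no mirror is
ever generated). Ties between permutations are broken by a fixed order
(identity first, then lexicographic), making results deterministic and
independent of scan order or any parallel partitioning.

The default match cutoff is max(2.5 Å, 1% of longest+shortest query
dimension). The formula is applied to the query cell *as supplied*, not
to its reduced cell — the natural reading of the rule, flagged here
because the alternative is defensible; `--cutoff` overrides it either
way.

## Family clustering

Pairwise identity = identical positions in the optimal global alignment
÷ shorter length. The alignment is shaped by match +1, mismatch 0,
affine gaps open −10 / extend −0.5 (a length-k gap costs
10 + 0.5·(k−1)); with these scores the gap penalty only prevents
spurious gapping and barely interacts with the identity count.
Clustering is greedy and CD-HIT-like: sequences sorted by descending
length (ties by sequence, then label), each joining the first cluster
whose representative matches at ≥ threshold (default 0.90, with a 1e-9
comparison slack so a pair at exactly the threshold merges), else
seeding a new cluster. Exact alignment is used instead of word-count
screening because per-query hit sets are tens of sequences, where
exactness and determinism are worth more than speed.

The composition vector multiplies asymmetric-unit chain counts by the
*primitive* operator count. The stored P1 cell is the primitive cell,
so its content is ASU × primitive operators; using conventional counts
would put the same crystal form deposited in centered vs primitive
settings into different families. Clustering is recomputed per query
over the hit set only — cluster ids are meaningful within one report.
Only the polymer chains present in an entry's chain list count toward
composition (no waters or ligands; nucleic-acid chains would count if
listed, but the generator and residue table are protein-centric).

## Database

Entries carry id, organism, method, cell, space group, R factors,
chain sequences, operator counts and the precomputed P1 cell (computed
once at ingest; queries never re-reduce database entries). Sources are
mmCIF headers (via gemmi.cif) or a one-row-per-entry TSV. Nonstandard
three-letter residue codes map through an embedded static table of
common modified residues (MSE→M, SEP→S, PTR→Y, ...; selenocysteine and
pyrrolysine map to their structural parents C and K to keep the 20+X
alphabet closed); unknown codes become X. Persistence is JSON Lines —
a header object with format version and table checksums, then entries
sorted by id — chosen for diffability and byte-stable round trips.

## Synthetic data

The fixture generator emulates a PDB metadata dump with known ground
truth. Cells are drawn per space group with crystal-system metric
constraints enforced exactly (tied parameters are perturbed jointly, so
a perturbed tetragonal cell still has a = b). Defaults: cell edges
uniform in 30–150 Å; near-copy jitter σ = 0.08 Å / 0.05° (the scale of
re-measurement differences between depositions of one crystal form);
decoy jitter 25 Å / 8°; 120-residue sequences, intra-family identity
0.95, uniform amino-acid background (~5% random identity, far below
the 0.90 threshold). Planted structure per group: one base, five
near-copies verified ≤ 0.5× the base's default cutoff, two decoys
verified ≥ 2×, one "coincident" entry (unrelated protein, near cell),
with all cross-group and background cells verified ≥ 2× every other
base's cutoff — so self-querying a base must recover exactly
{base, nears, coincidents}, split into families by content.

What this does **not** emulate: rounded cell parameters as deposited
(the TSV stores full precision so exact self-matches are testable),
realistic organism/R-factor distributions, sequence homology structure
beyond the planted families, nucleic acids, and the true density of
near-coincident cells in the PDB. Passing the recovery tests therefore
demonstrates correctness of the pipeline's logic, not the real-data
false-positive rate, which depends on how crowded cell space is.

## Problem sizes and determinism

Tests run the heavy properties at: 200 random point-set pairs against a
brute-force rotation-search oracle (1e-4 Å agreement), 1000 random
cells for Niggli idempotence/volume/unimodular invariance, and
end-to-end ground-truth recovery on five seeds with ~35-entry
databases. The acceptance script uses a one-entry database for the
self-match and a 100-residue pair scan for the clustering boundary.
All randomness flows from explicit seeds; identical inputs produce
byte-identical text and JSON reports.

## Known limitations

- Metric-symmetry exploration (detecting that a cell supports higher
  lattice symmetry, reindexing suggestions) is out of scope; the tool
  canonicalizes and matches, nothing more.
- Cells whose reduced forms sit near a Niggli type boundary can differ
  in their reduced *parameters* (not their match behavior) from tools
  that reduce with a different ε policy.
- The greedy clustering is order-deterministic but, like CD-HIT, not
  an optimal partition; a member is guaranteed ≥ threshold identity to
  its representative only.
- Sequence identity uses one optimal alignment; among co-optimal
  alignments the identity count can occasionally differ by a residue —
  irrelevant at the 90% threshold with realistic sequences.
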