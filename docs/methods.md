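# Methods

`coevnet` estimates a residue-coevolution network from a protein-family
multiple sequence alignment (MSA) and measures its architecture —
per-position centrality, windowed node weights, sub-network strength and
connectivity — against a column-shuffled null. This note documents the
model, its assumptions, the tunable parameters, and the design choices
made where the procedure was genuinely open.

## The estimator chain

Let the MSA have `N` sequences and `L` columns over the alphabet of 20
amino acids, an unknown symbol `X` and the gap `-` (22 symbols; gaps are
treated as a regular symbol everywhere, including entropies).

1. **Column masking.** Columns whose gap fraction exceeds
   `max_gap_fraction` (default 0.5) cannot be scored: deletion-tolerant
   segments of real families carry too few residues for pair statistics.
   Their rows/columns in the output matrix are NaN and are excluded from
   every count, mean and threshold downstream (this is why the number of
   scored elements `N_corr` of a block can be smaller than its
   off-diagonal size).
2. **Sequence weighting.** Identity clustering at fractional identity
   `theta = 0.62` (each sequence weighted `1/n_neighbours`); switchable
   to uniform weights.
3. **Pair frequencies.** Weighted joint symbol tables per column pair
   with a pseudocount of 1 per table cell.
4. **Mutual information.** `MI_ij = S_i + S_j - S_ij` in bits. The
   diagonal is set to the column self-information `S_i` and acts as the
   variance term of the matrix to be inverted. A joint-entropy-normalised
   variant (`nMI = MI / S_ij`) is available but **off by default**: at
   desk-scale depth the division inflates sampling noise at conserved
   columns and inverts the expected relation between entropy and null
   centrality (see "Null library" below).
5. **Average-product correction (APC).**
   `M_ij - mean_i(M) mean_j(M) / mean(M)` over off-diagonal entries,
   removing the rank-one background that finite depth and composition
   bias impose.
6. **Sparse inverse.** The corrected matrix is shrunk toward the
   identity with the smallest mixing weight giving minimum eigenvalue
   `>= 1e-3`, then inverted under an L1 penalty (graphical lasso,
   `rho = 1e-3`; `rho = 0` gives the dense inverse). The precision
   matrix suppresses indirect (transitive) correlations.
7. **Direct information.** `D_ij = W_ij / (W_ii W_jj)`. The off-diagonal
   entries of the precision matrix of a similarity matrix are *negative*
   for coupled pairs, so the assembled pipeline negates them
   (partial-correlation sign convention): coupled pairs score positive,
   which every downstream "positive correlation" count and upper-tail
   threshold assumes. The literal ratio remains available
   (`convention="raw"`).
8. **Column-mean normalisation.**
   `D'_ij = D_ij - (mean_i + mean_j)/2` with means over defined
   off-diagonal entries; this centres the distribution so that "positive"
   is meaningful. One pass roughly halves the spread of column means;
   exact zero means are not a fixed point and are not asserted.

## Null library

`K` column-shuffled copies of the alignment (default `K = 100`; the test
suite uses `K = 10–20` with correspondingly wider sampling tolerances)
are pushed through the identical chain. Shuffling preserves each
column's symbol multiset — hence its entropy and its gap fraction, so
the masked-column set is identical across members. The library stores:

- the pooled off-diagonal entry mean and sigma — the **3-sigma edge
  threshold** for high-scoring correlations;
- the per-position mean centrality `E_R` and its sigma;
- per-entry positive sums/counts, sufficient to build the randomized
  reference row for any sub-network selection;
- the pooled mean/sigma of null window weights — the **2-sigma
  primary-node threshold**.

Randomness: one master seed; member seeds derive from
`SeedSequence(entropy=seed, spawn_key=(member,))`, and each shuffle uses
a per-`(seed, column)` stream, so libraries are bit-reproducible and
column-order independent.

A property worth stating precisely: in real families the null centrality
profile covaries with column entropy mostly because deletion-tolerant
segments have both minimal entropy and no scoreable correlations. The
chain reproduces exactly that (masked segments have zero null
centrality). A *global* positive rank correlation between entropy and
null centrality across fully scored columns is **not** reproduced — APC
removes the rank-one entropy background by construction, and the L1
penalty preferentially suppresses couplings of high-entropy columns
(whose precision entries scale as `1/(S_i S_j)`). Tests assert the
mechanism, not the global correlation.

## Network measures

- **Centrality** (per position): the principal eigenvector `E` of the
  matrix with negatives clipped to zero (Perron–Frobenius guarantees a
  non-negative vector), unit L2 norm; the unclipped matrix remains in
  force for all sums. Masked columns get `E = 0`.
- **Node weights**: sliding windows of `n = 6` residues (stride 1),
  `W = mean(E)` per window; terminal truncated windows are excluded.
- **Difference profile**: `deltaW_i = E_i - (M_E/M_R) E_R,i` where
  `M_E/M_R` is the ratio of profile means; `mean(deltaW) = 0` exactly.
- **Primary nodes**: windows whose mean difference weight exceeds the
  null window mean by 2 sigma; overlapping windows merge into one node
  reported with its peak position.
- **Strength and connectivity** of a selection (block of the matrix):
  `S_M = (sum of positive values / count of positives)` and
  `C = (scored elements / dim1*dim2)`, each normalised by the single
  **global** randomized-library row — the convention recovered from the
  published per-domain tables, which normalise every row (intra-domain,
  inter-domain, contact, mutation-mask, 3-node) against one randomized
  row. Symmetric selections count both `(i,j)` and `(j,i)` and exclude
  the diagonal; `n_matrix = dim1*dim2` includes it, matching the printed
  table footnote.
- **3-node networks**: the top three primary nodes define three
  pairwise sub-networks; aggregates are summed over the three symmetric
  union blocks, so three 6-residue windows give
  `n_matrix = 3 x (6+6)^2 = 432`. This is the only convention consistent
  with the published 3-node rows (their scored-element counts exceed the
  strictly inter-node pair count).
- **Mutation masks**: a list of `m` mappable positions defines a binary
  mask with `m(m-1)` off-diagonal ones; significance comes from
  `n >= 100` (default 1000) dummy lists of equal cardinality drawn
  uniformly without replacement (contiguous-block sampling available),
  summarised as the dummy/real ratio distribution of `S_M` and `C` — the
  normalisation cancels in the ratio.
- **Autocorrelation**: mean-centred normalised autocorrelation of the
  centrality profile over integer residue lags; peaks near 3–4 and 7
  residues flag alpha-helical periodicity.

## Structure mapping

Structures are read from PDB (first model, one chain, highest-occupancy
altlocs, hetero/water skipped, residues without Calpha dropped). The
structure sequence is threaded into the MSA by global pairwise alignment
(BLOSUM62) against its closest row unless it is already present; residue
types must agree at every mapped position (hard error otherwise — the
correctness check for mapping high-scoring pairs onto structure).
Distance classes over Calpha–Calpha distances: contact `[0, 12)` Å,
intermediate `[12, 20]` Å, long-range `(20, inf)` Å — boundary values
fall on the non-contact side, matching the strict inequalities of the
source convention. Solvent accessibility is Shrake–Rupley (probe 1.4 Å,
960 golden-spiral points per atom by default; doubling the point count
changes per-residue areas by < 2%). Conserved surface patches are
maximal runs of > 4 columns where both a conservation score (by default
the entropy proxy `1 - S_i/max(S)`; any external per-column score can be
supplied) and accessibility strictly exceed their own profile means.
Superposition RMSD uses least-squares rigid-body alignment
(`scipy` rotation alignment; an independent Kabsch implementation serves
as the test oracle).

## Synthetic data

The generator emulates what the analysis needs from a Pfam-scale family,
at desk scale:

- **Depth/length**: default `N = 300`, `L = 120`.
- **Conservation gradient**: per-column target entropies (default
  linear 0.5 → 3.5 bits), realised by a one-dominant-symbol
  distribution whose dominant probability is solved by bisection.
- **Gap process**: independent per-cell gaps at a per-column rate
  (default 0.05; gap-heavy "deletion-tolerant" segments can be planted
  by passing a rate profile).
- **Coupling**: for a planted pair `(i, j, c)`, column `j` is a fixed
  bijective image of column `i` with probability `c` per sequence, else
  an independent draw — so `MI -> S_i` as `c -> 1`, analytically
  tractable and sufficient for rank-based recovery tests.
- **Reference bundle**: `N = 300`, `L = 120`, eight pairs at `c = 0.9` —
  two position-wise coupled 6-residue segments (columns 60–65 ↔
  100–105, the planted "nodes") plus two isolated pairs (30, 75) and
  (45, 90); seed documented per use (tests use seed 1).
- **Toy structure**: ideal alpha-helical Calpha trace (rise 1.5 Å,
  twist 100°, radius 2.3 Å), refolded by penalised least squares when
  planted contact (< 12 Å) / far (> 20 Å) constraints require it.
- **Mutation lists**: one list overlapping the planted coupled positions
  at a stated fraction, one uniform-random list of equal size.

What the generator does **not** emulate: phylogenetic correlation
between sequences (rows are exchangeable), insertion/deletion blocks
with realistic length distributions, and structural constraints linking
coupling to contacts. Passing tests therefore demonstrate that the
machinery recovers planted statistical signal under the stated
conditions, not that any biological conclusion transfers to real
families.

## Problem sizes and tolerances in the test suite

The suite runs the full chain at `N = 300, L = 120` with null libraries
of `K = 10` (recovery) and `K = 20` (library self-consistency, asserted
within `3/sqrt(K)` of unity). The mutation-asymmetry property uses 40
generator seeds with 150 dummy lists each. Published-table arithmetic is
checked to the printed 2-decimal precision wherever exact arithmetic
reproduces it; six cells whose printed values derive from the tables'
own *rounded* ratio columns are checked within 0.0065 (half an ulp at
the printed resolution plus printing slack), and the clockwise /
counter-clockwise mask strengths — whose published normalisation is not
derivable from the printed aggregates — are checked on connectivity
only.

## Known limitations

- The estimator is not the published contact-prediction binary; no
  byte-level agreement with it is attempted (only the documented
  matrix-level contracts).
- Per-complex vs per-domain normalisation of correlation values changes
  contact-statistics levels; both are possible by running the chain on
  the composite or the trimmed alignment, and the choice is the
  caller's.
- PDB input only (no mmCIF); first model only.
- Dummy-list sampling treats all scored positions as exchangeable;
  composition-matched dummies are not implemented.
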