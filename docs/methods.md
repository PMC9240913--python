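# Methods

## Contact definition

A residue–residue contact `a_ij = 1` is declared when the minimum distance
between atoms of the two residues is within the cutoff, read as a closed
bound: a pair at exactly 4.5 Å is in contact (tested explicitly at the
boundary). Crystal-ensemble analysis uses heavy atoms only at 4.5 Å —
hydrogens are stripped from all structures first, since protein hydrogens
are not deposited and mixed resolution would bias the counts. Snapshot
(simulation) ensembles are analysed all-atom, hydrogens included, at
4.2 Å. Both cutoffs, and the hydrogen policy, are parameters of every
contact routine; an ensemble whose ligand hydrogens were deposited can be
analysed with `hydrogen_policy="all_atom"` per structure if a user prefers
to keep them.

Sequentially neighbouring pairs (|i−j| ≤ 2) are never counted. The
separation is evaluated on author numbering, not on the rank of resolved
residues, so a gap of unresolved residues does not re-admit neighbours.
The exclusion is applied at matrix construction for every residue–residue
analysis, keeping a single matrix definition throughout; ligands carry no
sequence index, so residue–ligand contacts have no separation rule.

Residue–ligand fingerprints `L_i ∈ {0,1}` use the same geometric rule
between residue i and any atom of the structure's ligand entity. All
non-solvent hetero components of the selected chain are pooled into one
ligand entity per structure — fragment cocktails sharing a pocket count as
a single ligand — with a configurable exclusion list (waters, common ions
and cryo-buffers: HOH, NA, CL, SO4, GOL, EDO, PEG, …) applied first.

## Structure model

PDB text is parsed (via biotite) into a minimal model: ordered map of
integer author residue indices to heavy-atom lists for one polymer chain,
plus the pooled ligand entity. Alternate locations keep the
highest-occupancy conformer, ties broken by the alphabetically first
locator — a deterministic rule chosen for reproducibility. Insertion codes
are rejected loudly rather than silently renumbered, because every
downstream statistic is keyed on integer indices; entries with insertion
codes must be renumbered upstream. Unresolved residues are simply absent
and become all-zero rows in any window that covers them. Residue
renumbering is a pure index shift: internal simulation numbering (1–243)
maps onto canonical RORγ (UniProt P51449) numbering with +264 (A265–S507),
and RORγt-numbered entries map onto RORγ numbering with +21.

Multi-model PDB ensembles stream one frame at a time; frequency matrices
accumulate a running count, so trajectory length never bounds memory.
DCD/XTC reading goes through the optional mdtraj dependency.

## Dissimilarity and clustering

`N10(a, b)` counts cells where two binary maps differ; since entries are
binary, Σ(a−b)² is exactly the XOR count. Each unordered pair is counted
once (upper triangle); the whole-matrix convention, an exact factor of two,
is available behind a flag and cannot change any clustering. N10 is a
Hamming metric, verified by property tests (symmetry, identity, triangle
inequality) together with the conservation identity
N10 + 2·N11 = total(a) + total(b). The alternative `1/N11` dissimilarity is
infinite for maps sharing no contact; such pairs receive a sentinel of ten
times the largest finite distance in the matrix (10.0 if none), keeping
linkage well-defined while placing disjoint pairs strictly farthest.

Maps of heterogeneous entries are first restricted to the common window
276–475 (200×200) so every pair is compared on the same index set.
Synthetic two-state ensembles generated by this package share their full
window (265–507) natively and are clustered on it directly — the planted
activity-region signal lies above residue 475 by construction, so the
common-window restriction is a device for heterogeneous real entries, not
part of the dissimilarity definition.

Linkage defaults to average (UPGMA), the standard choice for
non-Euclidean dissimilarities; single and complete are available.
Structures are sorted lexicographically by id before linkage so merge
tie-breaks are reproducible run-to-run. Trees export to Newick under the
ultrametric convention (leaf height = merge height / 2).

## Activity classifier

Region 1 collects contacts with 300 < i < 340 and j > 475; region 2 those
with 470 < i < 495, i < j, j > 490. Inequalities are strict, taken
literally from the region definitions; each unordered pair counts once
with i the smaller index, and the two i-ranges are disjoint so no contact
is double-counted (asserted structurally). A combined count of 60 or more
is ACTIVE. With the uniform neighbour-exclusion convention, near-diagonal
region-2 pairs such as (489, 491) are excluded from the count; both the
cutoff and the exclusion are exposed for sensitivity analysis. A contact
map whose window ends before residue 476 cannot score region-1 contacts at
all; the classifier computes what it can and emits a warning, since the
resulting INACTIVE call may be an artefact of an unresolved C-terminus
rather than a conformational fact.

## Pocket profile and agonist score

Per-residue tallies N_A and N_I are restricted sums of L_i over the
ACTIVE/INACTIVE partition supplied (normally the classifier's own calls);
N_T = N_A + N_I. Pocket residues are those with N_T ≥ 10 by default. The
agonist contact score x = (N_A − N_I)/N_T is computed only where
N_T ≥ 10 (residues with N_T ≤ 9 are reported as filtered, avoiding
poor statistics and 0/0); it is antisymmetric under swapping class labels,
+1 for contacts exclusive to active structures, −1 for inactive-exclusive.
Residues with x below −0.5 (configurable) are reported as inverse-agonist
hot spots. The pocket-membership threshold and the score filter are
independent knobs even though both default to the same noise level.

Ligand size supports three definitions — heavy atoms (default, uniform
across entries once hydrogens are stripped), total atoms, and molecular
weight from standard atomic masses. Spread is reported as the population
SD (ddof = 0), a descriptive convention; ddof is configurable.

## Interaction PCA

The covariance of contact fluctuations C_ij = Σ_α δL_i^α δL_j^α / K
divides by the ensemble size K, not K − 1. Its diagonal is the Bernoulli
variance p_i(1 − p_i) of each residue's contact frequency — a property
test. Residues never contacted carry zero variance and enter the result
with zero loadings; the decomposition runs on the informative submatrix.
Modes sort by eigenvalue descending, exact ties broken by lexicographic
loading order; each eigenvector is oriented so its largest-magnitude
loading is positive, making plots reproducible run-to-run. An optional
orientation hook flips PC1 so a named subset of structures (e.g. known
allosteric binders) projects positively. Projections are of centred
fingerprints δL^α, so they have zero mean and per-mode variance equal to
the eigenvalue (ddof = 0) — both held to 1e−8 in tests, with eigenpairs
cross-checked against an independent power-iteration-with-deflation
oracle.

## Conserved contacts

Within one receptor, a contact is conserved between two ensembles when its
frequency is strictly above the threshold (default 0.5 — "more than half
the frames") in both; exactly 0.5 fails. Across receptors, contact pairs
route through a global Needleman–Wunsch alignment (Bio.Align), BLOSUM62
with gap open 10 / extend 0.5 by default, all configurable; the identity
count is reported together with its parameters since it depends on them.
A pair maps only if both residues align to non-gap positions; unmapped
pairs are reported separately rather than dropped silently. The
cross-receptor conserved set is symmetric under swapping receptors and
inverting the map (tested). A scatter table of all common pairs with both
frequencies and a conserved flag supports paired-frequency plots.

## Synthetic data

Each generator owns one `numpy` Generator seeded explicitly, so fixtures
are bit-reproducible and order-independent.

- **Coordinate fixtures** place single-atom residues so each requested
  pair sits at its exact distance while unlisted pairs stay ≥ 20 Å apart
  (disconnected constraint groups go on a 1000 Å grid). Geometrically
  infeasible requests — e.g. two short edges sharing a residue, which
  forces an unlisted pair close — raise an error rather than degrade.
- **Two-state ensembles** plant one activity-region contact prototype per
  class (default fills 70 vs 20, straddling the cutoff of 60 by a margin
  of 10 on each side — sizes chosen so class membership is unambiguous by
  construction, as in the real dichotomy); members perturb their prototype
  by count-preserving swaps (default 3), and all structures share one
  random non-region background at density 0.05, so clustering must find
  the planted signal rather than trivial size differences. Defaults use
  10 + 10 structures on window 265–507.
- **Binding-mode ensembles** draw fingerprints from two disjoint-support
  prototypes (12 residues each on a 50-residue window) with independent
  per-residue flips at ε = 0.05; ε ≥ 0.5 is rejected. The 50 + 50 default
  gives a clean two-mode covariance; a 123 + 9 split mirroring a small
  allosteric subset in a large ensemble is exercised in tests.
- **Bernoulli trajectories** sample each upper-triangle cell independently
  from a prescribed frequency matrix. 1000 frames put the empirical
  frequency within ±0.05 of the target elementwise (binomial
  concentration at p(1−p)/n ≤ 1/4000), which the tests assert.

What the generators deliberately do not emulate: real protein geometry
(no excluded volume, no chain connectivity beyond numbering), correlated
frame-to-frame dynamics (Bernoulli frames are independent), and the
partial-occupancy/disorder pathologies of crystallographic data beyond
altLoc records. Passing tests therefore certify the statistical machinery
and its thresholds, not structure-specific biology; conclusions about any
real receptor require running the pipeline on deposited coordinates.

## Problem sizes and numerical choices

The test suite and the acceptance script run on ensembles of 20–132
fingerprints, contact windows of ≤ 243 residues and 1000-frame
trajectories — ample for every statistic here, all of which are counts,
means or eigenproblems of ≤ 250×250 symmetric matrices. Distances use a
k-d tree with an inclusive radius; eigendecomposition is `numpy.eigh`;
degenerate inputs (empty matrices, single classes, disjoint maps, missing
C-termini) each have a documented behaviour and a test. Floating-point
ties at the contact cutoff follow the closed-bound reading.

## Known limitations

- Insertion-coded entries must be renumbered before use.
- mmCIF, assemblies and symmetry mates are out of scope; one chain per
  structure is analysed.
- The classifier inherits an INACTIVE bias for entries with unresolved
  C-termini (warned, not corrected).
- Cross-receptor conservation assumes both frequency matrices were built
  under the same contact convention; nothing enforces it across files.
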