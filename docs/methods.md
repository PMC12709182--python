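# Methods

## Contact definitions

Two residues of an RNA molecule are in contact under either of the two
conventions in common use:

* **nitrogen** — the glycosidic-face nitrogen atoms (N9 for purines A/G,
  N1 for pyrimidines C/U) are at most 9.5 Å apart. The comparison is
  inclusive (≤), reading "no more than" literally.
* **heavy** — the closest pair of non-hydrogen atoms of the two residues
  is strictly less than 10 Å apart.

Both thresholds and the strict/inclusive comparison are configurable.
Pairs with sequence separation |i − j| below `min_sep` are excluded as
trivial near-diagonal contacts. The exclusion width is not standardized
in the literature; the default of 4 removes the diagonal and its
immediate helix-neighbour bands and is recorded in every output header.
Contacts are stored as upper-triangle pairs (i, j), i < j, 1-based:
using both mirrored triangles would scale every kernel density by a
map-dependent factor and was rejected for canonicality.

Structure handling: the first model of multi-model entries is used;
alternate locations resolve to the highest-occupancy conformer (ties to
the earlier altloc letter); hydrogens are retained but flagged and never
enter heavy-mode distances; modified residues are mapped to their parent
nucleotide through a small editable table (e.g. PSU → U) and unmapped
names raise rather than guess. Multi-chain files are concatenated in
file order and renumbered 1..L, with original chain ids and author
numbers retained on each residue.

## The Gaussian score

For contacts C with positions r_i on the map,

    nu_i  = sum_{j in C} exp(−(r_i − r_j)² / σ²)
    omega_i = 1 / nu_i
    Omega  = sum_i omega_i

The self-term exp(0) = 1 is included in nu_i, which prevents divergence
of omega for isolated contacts and yields the clean bounds
omega ∈ (0, 1] and 1 ≤ Omega ≤ |C|. The kernel variance σ² = 4 (squared
index units) places the kernel's reach at a few residues — the scale of
helix runs and tertiary patches — and is the default everywhere.
Omega/L normalizes across molecule sizes.

The soft variant replaces the indicator with cell weights w ∈ [0, 1]:
nu(p) = Σ_q w_q·exp(−|r_p − r_q|²/σ²) and score = Σ_p w_p/nu(p). It
reduces exactly to the binary score when w is 0/1, and an all-zero map
scores 0 (there is nothing to weight). Cells with weight 0 are dropped
before the kernel sum, so predictors can pass dense probability maps
cheaply after thresholding.

## Cluster analysis and the selection schemes

Two contacts are in the same cluster if a path of adjacent contact
cells connects them. Adjacency is pixel adjacency on the map;
8-connectivity is the default because anti-diagonal helix runs step
diagonally and should form single clusters (4-connectivity is available
by flag). Clusters are reported in descending size, ties broken by the
lexicographically smallest member. No density-based or centroid
clustering is needed at this granularity.

Given a restraint budget n (default ⌊L/2⌋):

* **clustered** draws uniformly without replacement from the largest
  cluster until it is exhausted, then moves to the next cluster in
  descending-size order — the extreme of predictor-style clustering.
* **random** draws uniformly from the whole map.
* **gauss** maximizes Omega: the seed pair is the two contacts at
  maximal index distance, each greedy step adds the contact maximizing
  Omega of the augmented set, and a best-improvement single-swap hill
  climb runs until no exchange of one chosen for one unchosen contact
  increases Omega by more than 1e−12. The verifiable contract is
  single-swap local optimality; on small instances (|C| ≤ 12, n ≤ 4)
  the output matches exhaustive enumeration in ≈ 98 % of random trials
  and is never below 0.95× the optimum in the shipped checks. All ties
  break toward the lexicographically smallest contact, making the
  scheme fully deterministic; the seed argument exists only for
  interface symmetry.

Both stochastic schemes draw from a single seeded generator per
invocation; the CLI makes the seed mandatory.

## False contacts and evaluation

A selection of size |C| is diluted by adding
k = round(λ·|C|/(1−λ)) pairs drawn uniformly from the admissible
domain {(i, j): j − i ≥ min_sep} minus the native contacts (rounding is
half-away-from-zero so exact .5 requests are stable). The achieved
error rate k/(|C|+k) is recorded, and PPV = 1 − λ holds by
construction. λ ≥ 1 is rejected; so is a request exceeding the number
of free non-native pairs.

The **Hopkins statistic** measures the clustering tendency of the
selected contact positions. Per repetition, m = max(1, ⌈0.1·N⌉) probe
positions are drawn uniformly from the admissible index triangle (by
rejection sampling from the bounding square) and m data points are
sampled without replacement; with u the probe→nearest-data and w the
data→nearest-other-data Euclidean distances, H = Σu/(Σu + Σw). The
mean over 100 repetitions is returned; the sample fraction, repetition
count and domain are configurable and recorded. H ≈ 0.5 for
Poisson-random points, → 1 for strongly clustered sets. Note that
grid-like (regular) point sets score *below* 0.5 — regularity is the
opposite tail from clustering — so the null check uses uniform random
points, not a lattice.

The **beneficial fraction** ξ is the fraction of molecules whose
restrained RMSD is strictly lower than the unrestrained one; a tie is
not a benefit (Θ(0) = 0). Size-partitioned ξ splits at a residue-count
threshold with "small" meaning L ≤ threshold; an empty group's ξ is
reported as undefined (None), never coerced to 0.

The **RMSD** utility matches atoms by (chain, residue position, atom
name) — all common heavy atoms by default, or N1/N9 only to mirror the
contact definition — and superposes with the Kabsch algorithm
(reflections corrected through the SVD determinant). It is checked
against an independent quaternion (Horn) solution to 1e−9.

## Restraint export

Each selected contact becomes one record between the N1/N9 reference
atoms of its residues, with lower bound 0 and upper bound defaulting to
the contact threshold of the parent map (9.5 Å nitrogen / 10 Å heavy).
The penalty profile is flat-bottom with a constant cost beyond a cap
distance (default 2× the upper bound) so one badly violated restraint
cannot dominate the folding energy; the slope is folding-engine
configuration, so the writer emits the profile parameters as header
metadata instead of hard-coding energies. The generic column dialect
(chain, position, atom for each partner, then lower, upper, weight) is
byte-deterministic and round-trips through the bundled reader.

## Synthetic generators

The generators exist so every operation and property suite runs without
downloads; they emulate topology and minimal geometry, not physics.

* **Toy structures**: G–C ladder stems whose paired reference atoms sit
  8.5 Å apart (inside the nitrogen threshold) with a 3.1 Å rise, joined
  by hairpin loops displaced 12 Å sideways so loop residues create no
  stem contacts; helices are strung 60 Å apart. Hairpin loops need ≥ 3
  residues so the innermost pair clears min_sep = 4. Extraction
  recovers the designed pairing plus the ladder's geometric neighbours.
  Small coordinate jitter (σ = 0.05 Å) is seeded and deterministic.
* **Contact maps**: stems as anti-diagonal runs (the helix signature)
  plus circular Bernoulli patches emulating the blobs of convolutional
  predictor output. Stem cells are fully validated (in-domain, no
  overlap between stems); patch centers must be in-domain and candidate
  patch cells are clipped to the domain, since a patch is a stochastic
  request rather than an exact geometry.
* **RMSD tables**: unrestrained RMSDs uniform on 4–30 Å (the span of
  typical folding-run outcomes); restrained values differ by a fixed
  effect size (default 2 Å, floored at 0) downward with the stated
  improvement probability, else upward.

Passing tests on these fixtures demonstrate the algebraic and
statistical contracts (score bounds and closed forms, the PPV = 1 − λ
identity, scheme orderings of Omega and Hopkins, ξ recovery). They do
not demonstrate folding improvement on real molecules, which requires
running a folding engine with the exported restraints.

## Problem sizes and numerics

The shipped property suites use planted maps of L = 80 with ~100
contacts and 30 replicate maps for scheme-ordering checks, 1000 random
maps for score bounds, 50 small instances for the optimizer-vs-
enumeration comparison, and 500-row tables for ξ recovery; everything
runs in seconds on one CPU. Closed-form score checks are asserted to
1e−12, two-algorithm RMSD agreement to 1e−9, and exact counting
identities (PPV, λ) to 1e−12. Degenerate inputs (empty maps, empty
selections, single points, empty partition groups) raise typed errors
rather than returning sentinel numbers.

## Limitations

* Folding itself is out of scope: ξ on real molecules depends on the
  folding engine, and the restraint writer's penalty slope is left to
  engine configuration.
* The Gaussian-optimized scheme guarantees single-swap local, not
  global, optimality; global optimality is only verified on small
  instances.
* Hopkins parameters (10 % sample, 100 repetitions, uniform triangle
  probes) are one reasonable convention; absolute H values shift
  slightly under other conventions, though orderings are robust.
* The synthetic geometry is idealized; real structures contain missing
  atoms, heteroatoms and non-canonical pairs that only the
  modified-residue table partially addresses.
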