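# Methods

## Karyometric model

A metaphase spread is a set of measured chromosomes, each a (short arm,
long arm) pair in μm. Arms are canonicalized at read time (short ≤ long)
because measurement files do not guarantee arm order. Homolog pairing is
a minimum-weight perfect matching over the `2·n_pairs` longest
chromosomes; the edge weight is squared Euclidean distance in scaled
(total length, centromeric index) coordinates, with length divided by
the complement's mean chromosome length and CI by its full 0–50 range so
that neither axis dominates. Matching uses the exact blossom algorithm
(networkx); an exhaustive-enumeration oracle in the test suite confirms
optimality for complements of ≤ 8 chromosomes. Chromosomes beyond the
`2·n_pairs` longest are returned as leftover — in these taxa they are
candidate supernumerary (B) chromosomes, which are smaller than the
basic complement.

Pair identity across cells is positional: pairs are ranked by descending
length within each karyotype and the *k*-th ranked pairs are averaged
together. This mirrors how karyotype tables are built in practice, and
is the reason measurement noise must stay small relative to the length
gaps between adjacent pairs.

Statistics per pair use one value per karyotype (the mean of the two
homologs). Relative lengths are computed *within* each metaphase and
then averaged — not from the averaged absolute lengths. The distinction
matters: per-cell condensation scales all absolute lengths jointly, so
`mean(100·L/TCL)` ≠ `100·mean(L)/mean(TCL)` in general, and only the
former is condensation-invariant. SDs are sample SDs (divisor n − 1).

### Levan classification and the binary rule

CI bands: m (37.5, 50], sm (25, 37.5], st (12.5, 25], t (0, 12.5], with
band boundaries assigned to the lower class (CI = 37.5 → sm). The 95%
confidence interval of a pair's mean CI uses the Student t quantile with
n − 1 degrees of freedom rather than the normal quantile — at n = 10
karyotypes per population the difference is material — and is clipped to
the admissible (0, 50] range. If the interval spans a boundary the pair
receives a binary label, the mean's own class leading.

When one pair is reported jointly across several populations
(`classify_joint`), the unweighted pooled mean CI decides the leading
class and the label is binary if *any* population's interval spans a
boundary. This reconstruction reproduces the published joint
classification column for the three *S. nucleus* populations, including
the asymmetric `m-sm` vs `sm-m` labels of pairs 3 and 11.

### Interpopulation comparison

Pooled-variance (classical Student) two-sample t per pair and per
statistic, two-sided P from the t distribution with `n_a + n_b − 2` df,
flagged at a flat α = 0.05 with no multiple-testing correction across
pairs — each pair is treated as its own planned comparison, consistent
with how such karyotype comparisons are usually reported. Zero pooled
variance with equal means returns t = 0, P = 1.

## Ploidy categories

Against the modal diploid number *m*: exactly *m* → modal; below *m* →
hypodiploid; at or above `2m − 2` → polyploid (a doubled complement,
tolerating loss of up to 2 and any plausible B load); strictly between →
hyperdiploid with `b_count = count − m`. The polyploid band is a design
choice: doubled cells are rare and reported without per-cell detail, so
a tolerant band is preferable to an exact-`2m` rule. Hypodiploid and
polyploid cells are excluded from B-count distributions (their B status
is confounded) and from karyometric summaries (which use modal cells
only). The modal number itself must be a strict mode; ties raise an
error listing the tied values rather than guessing.

## Sequence distances

The number-of-differences distance counts sites where both sequences
carry *different unambiguous* bases (A/C/G/T after uppercasing and
U → T). Pairwise deletion excludes, per pair, any site with `-`, `?`,
`N` or an IUPAC ambiguity code in either member; ambiguity codes are
deliberately grouped with missing data rather than partially matched.
Group means are plain arithmetic means over all cross pairs (or all
unordered within-group pairs), which is what produces fractional
published values for multi-member groups. Haplotype collapsing requires
zero pairwise differences *and* an identical gap/missing pattern, so a
sequence with an internal gap never collapses with an ungapped one.

The bundled aligner is a Gotoh affine-gap global dynamic program
(default scores: match +1, mismatch −1, gap open −2, gap extend −0.5;
the first residue of a gap pays the open score). Traceback ties prefer
an aligned column over a gap, and a gap in the first sequence over a gap
in the second, making output deterministic. It is pairwise-only plumbing
for near-identical sequences; proper multiple alignments should be made
externally and read as aligned FASTA. Scores are cross-checked against
Biopython's `PairwiseAligner` in the test suite.

Neighbor joining (scikit-bio) with negative branch lengths clamped to
zero is provided to *visualize* a difference matrix; it is not a
substitute for model-based phylogenetic inference, which is outside this
package's scope.

## Synthetic data

`KaryotypeTruth` encodes a population's generative karyotype: per-pair
true total lengths (μm) and CIs, a B-chromosome size (default 2.5 μm,
metacentric-ish CI 45) and per-cell B-count distribution, probabilities
of hypodiploid (one chromosome lost) and tetraploid (doubled) cells, and
two noise scales. Per cell, a lognormal condensation factor with
median 1 (`sigma_condensation`, default 0.15 — chromosomes condense to
different degrees on different slides) multiplies every length; each arm
then gets independent lognormal measurement noise (`sigma_measure`,
default 0.02). Multiplicative, cell-wide condensation is exactly the
disturbance that relative statistics are designed to cancel, which the
simulation makes testable. The defaults for the built-in population
truths (`slovak_truth()` etc.) take the per-pair lengths/CIs from the
published summary tables and the B-count distribution, hypodiploid and
tetraploid rates from the published count tables (binned 34–35 columns
assigned to 34, except the Estonian split 18/2 which is known).

What the generator does *not* emulate: between-cell biological CI
dispersion beyond arm-measurement noise, correlated measurement errors
within an arm pair, staining artefacts, and observer bias in pairing.
Consequently, recovery tests show that the pipeline's estimators are
correct under the stated noise model — not that the model captures every
feature of real slides. One concrete instance: the published binary
label of *S. nucleus* pair 7 (CI 38.98 ± 4.99) requires CI spread that
multiplicative arm noise cannot produce without destroying the length
ranking, so generative tests assert a single `m` there while the
printed column is reproduced deterministically from the published
summary statistics.

`SeqTruth` builds gapped alignments from a uniform-random root plus
per-group planted substitutions and deletions; within-group copies are
identical. At every planted site the root is re-drawn from the unplanted
bases, so planted edits are guaranteed differences. Deletions are placed
away from variant sites (validated), so planted distances are exact by
construction, not merely in expectation. `truth_from_distance_matrix`
realizes an arbitrary symmetric integer matrix by decomposing it into
non-negative integer combinations of group partitions (≤ 4 blocks — one
base per block) via integer programming; a matrix violating realizability
(e.g. triangle inequality) raises rather than being approximated. This
is how the published 16S *S. nucleus* block, which is not additive in
private-site counts alone, is planted exactly.

## Numerical and interface choices

- Karyotype report TSVs print 2 decimals, matching the precision of
  published karyotype tables; round-tripping is exact at that precision.
- All randomness flows through one `numpy.random.Generator`; identical
  seed + truth gives identical output, and CLI outputs are byte-stable.
- Test problem sizes (10–100 cells, ≤ 8-chromosome matching oracles,
  20-mer alignment oracles, 11-replicate modal columns) are chosen so
  the whole suite runs in seconds while keeping sampling-error bounds
  (3 binomial SEs, 2–3 SEs for means) meaningful.
- Degenerate inputs fail loudly: empty tables, non-positive arms, tied
  modes, mismatched alignment lengths and unrealizable planted matrices
  all raise typed exceptions instead of producing silent defaults.

## Known limitations

- Homolog pairing is geometric; it cannot use banding patterns, and for
  pairs with near-identical lengths and CIs (as published for pairs 6/7
  and 9/10 of *S. nucleus*) positional identity across cells is partly
  arbitrary — exactly as in manual karyotyping.
- The binary-label reconstruction for jointly reported pairs is one
  defensible pooling rule; the original tabulations do not state theirs.
- Blanket "no significant interpopulation differences" statements cannot
  be verified from summary tables whose printed SDs imply otherwise for
  some pairs; the comparison machinery is tested on derived values
  instead.
- The aligner is quadratic-time pure Python: fine for a few hundred bp,
  not for genome-scale work.
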