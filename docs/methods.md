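# Methods

## Model and assumptions

A read of length L contributes L − k + 1 query k-mers. Against one target
(a reference genome, a clade, or a species), each query k-mer is treated as
an independent Bernoulli-type trial with outcomes "match at Hamming
distance d ∈ {0..δ}" or "miss". Three independent events produce a match:
the orthologous reference k-mer survived minimizer subsampling (probability
ρ), it accumulated exactly d substitutions at per-base distance D
(binomial: C(k,d) D^d (1−D)^{k−d}), and the bit-sampling LSH put query and
reference in the same bucket (C(k−h,d)/C(k,d)). The miss probability is the
complement, so P_miss + Σ_{d≤δ} P_match ≡ 1 holds algebraically — the
package treats this identity as a machine-precision invariant, not an
approximation.

The independence assumption is knowingly wrong for overlapping k-mers;
minimizer subsampling reduces (but does not remove) the overlap. The model
also assumes the lowest-HD match is the orthologous one (per position and
reference, only the minimum HD is kept) and ignores sequencing error.
Consequences observable in the tests: per-read estimates are noisy
(only ~122 trials per 150 bp read) with noise growing in D, and mid-range
distances are overestimated by a few percent relative (spurious
higher-HD matches from neighboring k-mers inflate the tail counts). Both
effects are within the ±0.01 absolute band the recovery tests assert.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| k | 29 | bases | k-mer length; 2k bits per encoded k-mer |
| w | 35 | bases | minimizer window; density ≈ 2/(w−k+2) = 25% of positions |
| h | 14 | positions | LSH bit-sampling arity; 2^(2h) buckets |
| δ | 4 | mismatches | max HD for a reported match |
| τ | 2 | — | placement support filter: unplaced if Σ_{i≤τ} v_i ≤ 1 |
| α | 0.10 | — | LRT significance; χ²(1) threshold ≈ 2.706 |
| seed | 1 | — | fixes the h sampled positions and the minimizer hash |

The sampled positions are drawn once per index (uniform, without
replacement) and serialized in the index header, so query-time hashing is
guaranteed to agree with build time. The minimizer hash is the MurmurHash3
64-bit finalizer applied to the 2k-bit split encoding XORed with a
seed-derived constant.

Concavity of the log-likelihood on (0, 0.5) holds for the default
(k, h, δ); for other configurations it is checked numerically at build
time (randomized histograms, second differences on a grid) and a warning
is emitted if violated, since the closed-form restrictions depend on the
configuration.

## Numerical choices

- Distance optimization: bounded Brent (`scipy.optimize.fminbound`) on
  [1e−6, 0.5 − 1e−6] with xtol 1e−8; estimates at a clamp are flagged
  (`at_bound`). Tests require agreement with a 10^4-point grid argmax to
  1e−4.
- Log-likelihood evaluates with fractional exponents (clade averaging
  yields fractional counts) and returns −inf, never NaN, when a positive
  count meets a zero probability.
- Histograms enforce count conservation u + Σ v = L − k + 1 to 1e−6
  (clade averaging is affine, so conservation is exact up to rounding).
- Canonical k-mers: the numerically smaller of the forward and
  reverse-complement encodings; canonicalization precedes minimizer
  hashing. Ties in a minimizer window go to the leftmost occurrence;
  windows containing any non-ACGT base contribute nothing (those query
  positions count as misses).
- Bucket boundaries: the index stores k-mers sorted by the combined
  (bucket, payload) key and recovers bucket slices by binary search. A
  dense cumulative offset array of size 2^(2h) is available
  (`offset_index()`) and tested for small h; for the default h = 14 the
  dense array would dwarf the k-mer payloads themselves at small reference
  scales, and the binary search yields identical slices.
- Distant-genome prefilter: references whose best observed HD exceeds the
  global best by more than 2 are dropped before estimation (never dropping
  all); the gap is configurable and gap = δ disables the filter.
- Color-union lookup: 128-bit per-reference keys, addition mod 2^128 as
  the Abelian group; every key hit is verified by comparing resolved sets,
  so a hash collision can never merge two distinct colors.
- Color height: 0 for singletons and for colors whose member set equals a
  clade of the guiding tree; otherwise 1 + max over children. Unobserved
  intermediate colors are kept (cheap at these scales).
- Ties in placement: the minimum-distance clade prefers larger clades and
  then preorder index; the chosen clade prefers larger, then smaller
  distance, then preorder index. Root selection maps to "unplaced" — no
  synthetic root edge is ever emitted.

## The synthetic-data generator

`lshplace.simulate` emulates the conditions the estimator is meant for:
Jukes–Cantor substitutions (uniform among the three alternatives, no
indels) with Gamma(shape 5, mean 1, variance 1/5) rate multipliers drawn
once per 1 kb region, ~5% of regions intergenic and mutation-free, target
genome-wide distances up to 0.3, and fixed-length reads (150 bp) sampled
uniformly from both strands. Optional uniform sequencing error is applied
after the true distance is recorded. Because there are no indels, all
genomes share coordinates, and every read's true distance to every genome
is exactly recomputable from stored mutation positions — this is the
ground-truth contract behind all recovery tests.

What the generator does *not* emulate: indels and rearrangements,
repetitive and low-complexity sequence, realistic error profiles,
horizontal transfer, and compositional bias. Passing recovery tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not performance on real genomes.

Problem sizes used by the test suite: 1 Mb sequences for density checks,
60 kb genomes with 500 reads per distance level for estimator recovery,
6–12 leaf trees with 3–20 kb genomes and 200 reads for placement checks.
These sizes put all Monte-Carlo checks within their stated tolerances
while keeping the default suite fast.

## Design decisions on genuinely open points

- **Query-side k-mers.** All L − k + 1 canonical read k-mers are queried
  (not read minimizers): the likelihood counts L − k + 1 trials and ρ
  already accounts for reference-side subsampling. Querying read
  minimizers instead would require a different trial count and a
  query-side retention model.
- **ρ as distinct/distinct.** ρ_r is the count of distinct selected
  minimizers over distinct canonical k-mers; mixing occurrences with
  distinct counts would bias ρ for repetitive references.
- **Noise-free placement fixtures.** The exact-recovery placement check
  builds expectation-valued histograms on an ultrametric tree. The
  construction uses ρ = 0.5: at sparser subsampling the deepest grafts
  carry so little information that the LRT — operating exactly as designed
  — keeps the root statistically tied, and no placement rule could resolve
  them. The recovery property is about the placement logic, so the fixture
  sits inside the resolvable regime (recovery is then exact at every tree
  depth scale probed).
- **Species-level aggregation.** Species histograms average member
  genomes' v, u and ρ; above the species level the clade rule applies
  (mean v, max ρ). The two aggregation rules are intentional: species
  members are interchangeable representatives, clade children are not.
- **LRT orientation.** The statistic is 2(l_∅ − l_A) ≥ 0, with both terms
  evaluated on the best clade's histogram (l_∅ at its own maximizer), so
  the χ²(1) reference distribution applies on the correct support.

## Known limitations

- Placement is branch-length-agnostic; strongly non-ultrametric trees
  carry no formal guarantee.
- The miss model treats LSH false negatives as independent across
  positions; correlated misses (e.g., clustered mutations) are not
  modeled.
- Estimates at the 1e−6 clamp mean "at or below resolution", not a
  genuine zero-distance estimate.
- Very distant targets (D approaching 0.3+) yield few matches and
  unstable estimates; the distant-genome prefilter and the τ filter
  exist to keep such targets from polluting placements.
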