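# lshplace

Alignment-free estimation of the distance between short sequencing reads
and a collection of reference genomes, and placement of each read onto a
rooted reference phylogeny or taxonomy. The intended users are
metagenomics practitioners who want per-read, genome-wide evidence —
not just marker genes — about where a read's source organism sits relative
to a reference tree, at scales where read-to-genome alignment is too
costly or too insensitive.

## The method

**Inexact k-mer matching.** Reference genomes are summarized by canonical
minimizers (k = 29 within windows of w = 35 bases, the k-mer with the
smallest hash per window; about 25% of k-mer positions survive). Each
stored k-mer is bucketed by a locality-sensitive hash: its 2-bit base codes
at h = 14 fixed, randomly chosen positions. A query k-mer is compared, at
exact Hamming distance (HD), only against the k-mers in its own bucket,
and matches with HD ≤ δ = 4 are kept. Two k-mers at HD = d share a bucket
with probability

    P_collide(d; k, h) = C(k−h, d) / C(k, d),

so close matches are found with high probability while distant ones are
cheaply ignored. A color multitree — a binary DAG with disjoint children,
grown along a post-order traversal of the reference tree — maps every
stored k-mer to the exact set of genomes containing it.

**Maximum pseudo-likelihood distance.** For a read of length L, each of
its L − k + 1 k-mers either matches reference r at some HD d ≤ δ or
misses. Treating k-mers as independent, the match counts v = (v_0, …, v_δ)
and miss count u = L − k + 1 − Σ v_d are sufficient, and the likelihood of
a per-base distance D is

    L_r(D) = P_miss(D)^u · Π_d P_match(D; d)^{v_d},
    P_match(D; d) = ρ_r · C(k, d) D^d (1−D)^{k−d} · P_collide(d; k, h),
    P_miss(D)     = 1 − Σ_{d≤δ} P_match(D; d),

where ρ_r is the fraction of r's distinct k-mers kept by minimizer
subsampling. The log-likelihood is concave on (0, 0.5) for the default
(k, h, δ) and is maximized by bounded Brent search.

**Placement.** Histograms extend to clades bottom-up (v averaged over
children, ρ the max), giving every clade a distance and a log-likelihood.
A χ²(1 df) likelihood-ratio test on 2(l_∅ − l_A) finds all clades
statistically indistinguishable from the minimum-distance clade C_∅; the
read is placed as sister to the largest such clade (ties → smallest
distance), or left unplaced when that clade is the root or has too few
close matches (Σ_{i≤τ} v_i ≤ 1, τ = 2). Output is jplace v3 with the
attachment at the branch midpoint (distal = branch/2, pendant = 0).

## Worked example

`examples/estimate_read_distances.py` builds an index over a 60 kb
reference, evolves a copy to 5% divergence, and estimates per-read
distances for 300 error-free 150 bp reads:

```
indexed 14889 minimizer k-mers (rho = 0.248)
evolved genome: true distance = 0.0522
mapped 297/300 reads
mean estimated distance: 0.0591 (mean true per-read distance: 0.0526)
per-read RMSE: 0.0183
```

The mean estimate tracks the true distance; single reads are noisy because
each carries only 122 k-mer trials. `examples/place_reads.py` does a
leave-one-out placement on a 10-taxon simulated tree:

```
backbone: 9 references, index: 43328 k-mers
placed 49/50 reads -> scratch_example.jplace
example placement: edge 10 (sister to clade of R5,R6), distance 0.0937, 2 tied candidate(s)
```

The other examples show the color multitree's structure
(`explore_color_multitree.py`) and rank-adaptive taxonomic assignment
(`taxonomic_placement.py`). A thin CLI wraps the same library calls:

```bash
lshplace sim refset -o refs.fa --n-refs 8          # synthetic references
lshplace build -i refs/ -t tree.nwk -o index/      # build the index
lshplace dist  -i index/ -q reads.fq.gz -o out.tsv # per-read distances
lshplace place -i index/ -q reads.fq.gz -t tree.nwk -o out.jplace
```

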