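"""Leave-one-out phylogenetic placement of simulated reads.

Simulates ten reference genomes down a random tree, removes one reference,
indexes the rest, and places reads from the removed genome back onto the
pruned tree. Correct behavior is placement on (or next to) the branch where
the pruned genome used to attach; the jplace file records each placement's
edge, distance, and tie weights.
"""

import dendropy

from lshplace import (EncodingParams, Phylogeny, QueryParams,
                      clade_histograms, collect_read_matches, place_read,
                      simulate_reads, simulate_reference_set, write_jplace)
from lshplace.index import build_index_from_seqs

params, qparams = EncodingParams(), QueryParams()

tree, genomes, _anc = simulate_reference_set(
    10, tree_shape_seed=4, genome_len=20_000, depth_scale=0.04)
query = "R3"
pruned_dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
pruned_dt.prune_taxa_with_labels([query])
backbone = Phylogeny.from_newick(pruned_dt.as_string(schema="newick").strip())

index = build_index_from_seqs(
    {r: g.sequence for r, g in genomes.items() if r != query},
    backbone, params, qparams)
rho = {r: m.rho for r, m in index.ref_meta.items()}
print(f"backbone: {len(backbone.leaves)} references, "
      f"index: {len(index)} k-mers")

reads = simulate_reads(genomes[query], L=150, n=50, seed=5, genome_id=query)
results, placed = {}, 0
for read in reads:
    hists = collect_read_matches(index, read.sequence)
    scores = clade_histograms(backbone, hists, 150, rho,
                              params.k, params.h, qparams.delta)
    res = place_read(scores, backbone, alpha=qparams.alpha,
                     tau=qparams.tau, h=params.h)
    results[read.read_id] = res
    placed += res.status == "placed"

write_jplace(results, backbone, "scratch_example.jplace")
print(f"placed {placed}/{len(reads)} reads -> scratch_example.jplace")

sample = next(r for r in results.values() if r.status == "placed")
target = (sample.node.label if sample.node.is_leaf
          else "clade of " + ",".join(sorted(
              l.label for l in sample.node.children if l.is_leaf)))
print(f"example placement: edge {sample.edge} (sister to {target}), "
      f"distance {sample.d_hat:.4f}, {len(sample.tied)} tied candidate(s)")
# Reads from the pruned genome should land on its former sister lineage;
# ties reflect clades the likelihood-ratio test cannot separate.
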