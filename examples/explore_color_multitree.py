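"""Inspect the color multitree behind an index.

Builds a small index over six related genomes and reports how shared
k-mers are represented: most colors coincide with clades of the reference
tree (height 0); k-mers shared by non-sister genomes need meta-colors.
"""

from lshplace import EncodingParams, QueryParams, multitree_stats
from lshplace.colors import assign_colors_postorder
from lshplace.encoding import minimizer_positions
from lshplace.index import build_index_from_seqs
from lshplace.simulate import simulate_reference_set

params, qparams = EncodingParams(), QueryParams()

tree, genomes, _anc = simulate_reference_set(
    6, tree_shape_seed=2, genome_len=5_000, depth_scale=0.02)
per_ref = {r: minimizer_positions(g.sequence, params)[1]
           for r, g in genomes.items()}
assignment, multitree = assign_colors_postorder(tree, per_ref,
                                                key_seed=params.seed)

stats = multitree_stats(multitree, assignment)
print(f"references: {stats['n_singletons']}, "
      f"internal colors: {stats['n_internal']} "
      f"({stats['n_unobserved']} unobserved)")
print(f"height distribution over k-mers: {stats['height_distribution']}")
print(f"mean color height: {stats['mean_height']:.4f}")

shared = [c for c in set(assignment.values())
          if len(multitree.resolve(c)) > 1]
example = max(shared, key=lambda c: len(multitree.resolve(c)))
print(f"largest shared color resolves to {sorted(multitree.resolve(example))}")
# Height 0 means a k-mer's genome set is exactly a clade of the tree; small
# mean heights are what make color resolution cheap at query time.
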