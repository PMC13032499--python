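"""Place a read on a multifurcating taxonomy with species as leaves.

Two species of one genus and two of another, each species backed by one
genome. A read whose matches tie the two species of genus A lands on the
genus A branch; a read matching only one species lands on that species
leaf.
"""

import numpy as np

from lshplace import MatchHistogram, Phylogeny, TaxonomyTree, place_taxonomic
from lshplace.distance import p_match

K, H, DELTA, L = 29, 14, 4, 150
TRIALS = L - K + 1

taxonomy = TaxonomyTree(
    tree=Phylogeny.from_newick(
        "((spA1:1,spA2:1)genusA:1,(spB1:1,spB2:1)genusB:1);"),
    species_map={"gA1": "spA1", "gA2": "spA2", "gB1": "spB1", "gB2": "spB2"})
rho = {g: 0.25 for g in taxonomy.species_map}


def hist(D):
    v = np.array([TRIALS * p_match(D, d, K, H, 0.25) for d in range(DELTA + 1)])
    return MatchHistogram(v=v, u=TRIALS - v.sum(), rho=0.25, L=L, k=K)


# read equally close to both genus-A species: genus-level assignment
res = place_taxonomic({"gA1": hist(0.05), "gA2": hist(0.05)}, taxonomy,
                      L, rho, K, H, DELTA)
label = res.node.label or "?"
print(f"ambiguous within genus A -> placed on: {label} ({res.status}, "
      f"distance {res.d_hat:.4f})")

# read clearly closest to a single species: species-level assignment
res = place_taxonomic({"gA1": hist(0.01), "gA2": hist(0.15)}, taxonomy,
                      L, rho, K, H, DELTA)
print(f"unambiguous -> placed on: {res.node.label} ({res.status}, "
      f"distance {res.d_hat:.4f})")
# The likelihood-ratio test decides the rank: indistinguishable species
# push the placement one rank up, to their shared taxon branch.
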