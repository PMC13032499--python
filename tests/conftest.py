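"""Shared fixtures: toy reference sets with brute-force oracles.

All fixtures are generated programmatically with fixed seeds; the brute
force dictionary oracle maps every indexed k-mer value to the exact set of
references carrying it, independently of the index/color machinery.
"""

from collections import defaultdict

import numpy as np
import pytest

from lshplace import EncodingParams, Phylogeny, QueryParams
from lshplace.encoding import minimizer_positions
from lshplace.index import build_index_from_seqs
from lshplace.simulate import simulate_reference_set


@pytest.fixture(scope="session")
def params():
    return EncodingParams()  # k=29, w=35, h=14, seed=1


@pytest.fixture(scope="session")
def qparams():
    return QueryParams()  # delta=4, tau=2, alpha=0.10


@pytest.fixture(scope="session")
def toy_refset():
    """Six references of ~3 kb evolved down a random tree (close enough to
    share plenty of k-mers) plus the tree and ancestor."""
    tree, genomes, anc = simulate_reference_set(
        6, tree_shape_seed=11, genome_len=3000, depth_scale=0.02)
    seqs = {r: g.sequence for r, g in genomes.items()}
    return tree, seqs, genomes, anc


@pytest.fixture(scope="session")
def toy_index(toy_refset, params, qparams):
    tree, seqs, _genomes, _anc = toy_refset
    return build_index_from_seqs(seqs, tree, params, qparams)


@pytest.fixture(scope="session")
def toy_oracle(toy_refset, params):
    """Brute-force k-mer -> reference-set dictionary over the minimizers of
    each toy reference."""
    _tree, seqs, _genomes, _anc = toy_refset
    oracle = defaultdict(set)
    for ref, seq in seqs.items():
        _pos, vals = minimizer_positions(seq, params)
        for v in np.unique(vals).tolist():
            oracle[int(v)].add(ref)
    return dict(oracle)


@pytest.fixture(scope="session")
def star_tree_3():
    return Phylogeny.from_newick("(A:1,B:1,C:1);")
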