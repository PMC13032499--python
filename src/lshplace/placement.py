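"""Phylogenetic and taxonomic read placement via a likelihood-ratio test.

Per-reference match histograms are extended to clades bottom-up: an
internal clade's histogram is the arithmetic mean of its children's
(``v_C = mean(v_children)``, misses follow by count conservation) and its
subsampling rate is the max over children. Each clade with at least one
match gets a maximum pseudo-likelihood distance. A chi-square(1) likelihood
ratio test — statistic ``2 (l_0 - l_A)`` where both log-likelihoods use the
best clade's histogram as data — decides which clades are statistically
indistinguishable from the minimum-distance clade. The read is placed as
sister to the largest indistinguishable clade (ties broken by smaller
distance); it is left unplaced when that clade is the root or when it has
too few low-distance matches (``sum_{i<=tau} v[i] <= 1``). The reported
attachment point is the midpoint of the chosen clade's parent branch
(distal = branch/2) with pendant length 0, for jplace compatibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .distance import (DistanceEstimate, MatchHistogram, NoMatchesError,
                       estimate_distance, log_likelihood)

__all__ = [
    "Phylogeny", "PhyloNode", "CladeScore", "PlacementResult", "TaxonomyTree",
    "clade_histograms", "lrt_distinguishable", "place_read",
    "multiplacement_weights", "closest_reference", "place_taxonomic",
    "indistinguishable_leaf_set", "write_jplace",
]


class PhyloNode:
    __slots__ = ("index", "parent", "children", "length", "label", "edge_num",
                 "_n_leaves")

    def __init__(self, index: int, parent: "PhyloNode | None", length: float | None,
                 label: str | None):
        self.index = index
        self.parent = parent
        self.children: list[PhyloNode] = []
        self.length = length
        self.label = label
        self.edge_num: int | None = None
        self._n_leaves: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n_leaves(self) -> int:
        if self._n_leaves is None:
            self._n_leaves = 1 if self.is_leaf else sum(
                c.n_leaves for c in self.children)
        return self._n_leaves

    def __repr__(self):
        tag = self.label if self.label else f"node{self.index}"
        return f"<PhyloNode {tag}>"


class Phylogeny:
    """A rooted (possibly multifurcating) tree with stable preorder node
    indices and jplace edge numbering (one edge per non-root node)."""

    def __init__(self, root: PhyloNode):
        self.root = root
        self.nodes: list[PhyloNode] = []
        self._index_nodes()

    def _index_nodes(self):
        self.nodes = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        edge = 0
        for node in self.nodes:
            if node.parent is not None:
                node.edge_num = edge
                edge += 1
            node._n_leaves = None

    @property
    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def node_by_label(self, label: str) -> PhyloNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def postorder(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []
        stack: list[tuple[PhyloNode, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        return out

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node.index] = frozenset([node.label])
            else:
                sets[node.index] = frozenset().union(
                    *(sets[c.index] for c in node.children))
        return sets

    # -- Newick I/O (via dendropy) ------------------------------------------

    @classmethod
    def from_newick(cls, source: str, rooted_required: bool = True) -> "Phylogeny":
        """Parse a Newick tree from a path or a literal Newick string."""
        import dendropy

        if source.lstrip().startswith("(") or source.rstrip().endswith(";"):
            dtree = dendropy.Tree.get(data=source, schema="newick")
        else:
            dtree = dendropy.Tree.get(path=source, schema="newick")
        droot = dtree.seed_node
        if rooted_required and len(droot.child_nodes()) > 2:
            import warnings
            warnings.warn("root has more than two children; treated as a "
                          "multifurcation at the root")

        def _convert(dnode, parent):
            label = dnode.taxon.label if dnode.taxon is not None else (
                dnode.label or None)
            node = PhyloNode(0, parent, dnode.edge.length, label)
            for dc in dnode.child_nodes():
                node.children.append(_convert(dc, node))
            return node

        return cls(_convert(droot, None))

    def to_newick(self, edge_numbers: bool = False) -> str:
        def _fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.parent is not None:
                length = node.length if node.length is not None else 0.0
                s += f":{length:.10g}"
                if edge_numbers:
                    s += f"{{{node.edge_num}}}"
            return s

        return _fmt(self.root) + ";"


@dataclass
class CladeScore:
    node: PhyloNode
    hist: MatchHistogram
    d_hat: float | None
    loglik: float | None
    n_leaves: int


@dataclass
class PlacementResult:
    status: str                       # "placed" | "unplaced" | "unmapped"
    node: PhyloNode | None = None
    edge: int | None = None
    d_hat: float | None = None
    tied: list[tuple[PhyloNode, float]] = field(default_factory=list)
    tied_loglik: list[float] = field(default_factory=list)
    distal: float | None = None
    pendant: float = 0.0


@dataclass
class TaxonomyTree:
    """A multifurcating taxonomy whose leaves are species, each backed by
    one or more reference genomes."""

    tree: Phylogeny
    species_map: Mapping[str, str]  # genome id -> species leaf label

    def __post_init__(self):
        species = set(self.tree.leaf_labels)
        bad = {g for g, s in self.species_map.items() if s not in species}
        if bad:
            raise ValueError(f"genomes mapped to unknown species: {sorted(bad)}")

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {s: [] for s in self.tree.leaf_labels}
        for g, s in self.species_map.items():
            out[s].append(g)
        return out


def clade_histograms(
    tree: Phylogeny,
    leaf_hists: Mapping[str, MatchHistogram],
    L: int,
    rho_by_leaf: Mapping[str, float],
    k: int,
    h: int,
    delta: int,
) -> dict[int, CladeScore]:
    """Bottom-up clade histograms and distance estimates for every node.

    Leaves without matches contribute an all-miss histogram at their indexed
    subsampling rate. Internal nodes average children's ``v`` (equal
    weights) and take the max ``rho``. Nodes with no matches at all get no
    distance estimate.
    """
    if not leaf_hists:
        return {}
    scores: dict[int, CladeScore] = {}
    trials = L - k + 1
    for node in tree.postorder():
        if node.is_leaf:
            hist = leaf_hists.get(node.label)
            if hist is None:
                hist = MatchHistogram.empty(delta, rho_by_leaf[node.label], L, k)
        else:
            child_hists = [scores[c.index].hist for c in node.children]
            v = np.mean([ch.v for ch in child_hists], axis=0)
            hist = MatchHistogram(
                v=v, u=trials - float(v.sum()),
                rho=max(ch.rho for ch in child_hists), L=L, k=k)
        d_hat = loglik = None
        if hist.n_matches > 0:
            est = estimate_distance(hist, h)
            d_hat, loglik = est.d_hat, est.loglik
        scores[node.index] = CladeScore(
            node=node, hist=hist, d_hat=d_hat, loglik=loglik,
            n_leaves=node.n_leaves)
    return scores


def lrt_distinguishable(best: CladeScore, other: CladeScore, alpha: float,
                        h: int = 14) -> bool:
    """Chi-square(1) likelihood-ratio test of whether ``other``'s distance is
    statistically distinguishable from the best clade's.

    Both log-likelihoods are evaluated on the best clade's histogram: l_0 at
    the best distance (its maximizer) and l_A at the other clade's distance,
    so the statistic 2(l_0 - l_A) is nonnegative.
    """
    l0 = best.loglik
    lA = log_likelihood(other.d_hat, best.hist, h)
    stat = max(0.0, 2.0 * (l0 - lA))
    return stat > chi2.ppf(1.0 - alpha, df=1)


def _scored(scores: Mapping[int, CladeScore]) -> list[CladeScore]:
    return [s for s in scores.values() if s.d_hat is not None]


def _best_clade(cands: Sequence[CladeScore]) -> CladeScore:
    # minimum distance; ties -> larger clade, then preorder index
    return min(cands, key=lambda s: (s.d_hat, -s.n_leaves, s.node.index))


def place_read(
    scores: Mapping[int, CladeScore],
    tree: Phylogeny,
    alpha: float = 0.10,
    tau: int = 2,
    h: int = 14,
    with_weights: bool = True,
) -> PlacementResult:
    """Choose the placement clade by the largest-indistinguishable rule."""
    cands = _scored(scores)
    if not cands:
        return PlacementResult(status="unmapped")
    best = _best_clade(cands)
    tied = [s for s in cands
            if s is best or not lrt_distinguishable(best, s, alpha, h)]
    chosen = min(tied, key=lambda s: (-s.n_leaves, s.d_hat, s.node.index))
    weights: list[tuple[PhyloNode, float]] = []
    lls: list[float] = []
    if with_weights:
        weights = multiplacement_weights(best, tied, h)
        lls = [log_likelihood(s.d_hat, best.hist, h) for s in tied]
    low_matches = float(chosen.hist.v[: tau + 1].sum()) <= 1.0
    if chosen.node.parent is None or low_matches:
        return PlacementResult(status="unplaced", node=chosen.node,
                               d_hat=chosen.d_hat, tied=weights, tied_loglik=lls)
    length = chosen.node.length if chosen.node.length is not None else 0.0
    return PlacementResult(
        status="placed", node=chosen.node, edge=chosen.node.edge_num,
        d_hat=chosen.d_hat, tied=weights, tied_loglik=lls,
        distal=length / 2.0, pendant=0.0)


def multiplacement_weights(
    best: CladeScore, candidates: Sequence[CladeScore], h: int
) -> list[tuple[PhyloNode, float]]:
    """Normalized pseudo-likelihood weights of the tied candidate clades,
    each evaluated on the best clade's histogram at the candidate's own
    distance."""
    lls = np.array([log_likelihood(s.d_hat, best.hist, h) for s in candidates])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    return [(s.node, float(wi)) for s, wi in zip(candidates, w)]


def closest_reference(leaf_estimates: Mapping[str, DistanceEstimate]) -> str:
    """The minimum-distance reference (ties: more matches, then id order)."""
    if not leaf_estimates:
        raise NoMatchesError("no reference estimates; read is unmapped")
    return min(leaf_estimates.items(),
               key=lambda kv: (kv[1].d_hat, -kv[1].n_matches, kv[0]))[0]


def indistinguishable_leaf_set(
    leaf_scores: Mapping[str, CladeScore], alpha: float, h: int = 14
) -> set[str]:
    """All leaves whose distances fail the LRT against the minimum-distance
    leaf (an OGU-style multi-assignment)."""
    scored = {r: s for r, s in leaf_scores.items() if s.d_hat is not None}
    if not scored:
        return set()
    best = _best_clade(list(scored.values()))
    return {r for r, s in scored.items()
            if s is best or not lrt_distinguishable(best, s, alpha, h)}


def place_taxonomic(
    read_hists: Mapping[str, MatchHistogram],
    taxonomy: TaxonomyTree,
    L: int,
    rho_by_genome: Mapping[str, float],
    k: int,
    h: int,
    delta: int,
    alpha: float = 0.10,
    tau: int = 2,
) -> PlacementResult:
    """Placement on a multifurcating taxonomy with species as leaves.

    Species-level histograms are the arithmetic means of the member
    genomes' (v, u) with the mean subsampling rate; above the species level
    the usual clade combination (mean v, max rho) applies.
    """
    members = taxonomy.members()
    trials = L - k + 1
    species_hists: dict[str, MatchHistogram] = {}
    species_rho: dict[str, float] = {}
    for sp, genomes in members.items():
        if not genomes:
            raise ValueError(f"species {sp!r} has no member genomes")
        rho = float(np.mean([rho_by_genome[g] for g in genomes]))
        species_rho[sp] = rho
        hists = [read_hists.get(g) for g in genomes]
        if all(hh is None for hh in hists):
            continue
        hists = [hh if hh is not None
                 else MatchHistogram.empty(delta, rho_by_genome[g], L, k)
                 for g, hh in zip(genomes, hists)]
        v = np.mean([hh.v for hh in hists], axis=0)
        species_hists[sp] = MatchHistogram(
            v=v, u=trials - float(v.sum()), rho=rho, L=L, k=k)
    if not species_hists:
        return PlacementResult(status="unmapped")
    scores = clade_histograms(
        taxonomy.tree, species_hists, L, species_rho, k, h, delta)
    return place_read(scores, taxonomy.tree, alpha=alpha, tau=tau, h=h)


def write_jplace(
    results: Mapping[str, PlacementResult], tree: Phylogeny, path: str
) -> None:
    """Write placed reads as a jplace (version 3) JSON file.

    Fields per placement row: edge number, pseudo-log-likelihood at the
    placement, normalized like_weight_ratio, distal length (half the chosen
    branch), and pendant length (always 0).
    """
    placements = []
    for read_id, res in results.items():
        if res.status != "placed":
            continue
        tied = res.tied or [(res.node, 1.0)]
        lls = res.tied_loglik or [0.0] * len(tied)
        rows = []
        for (node, weight), ll in zip(tied, lls):
            if node.parent is None:
                continue
            length = node.length if node.length is not None else 0.0
            rows.append([node.edge_num, float(ll), weight, length / 2.0, 0.0])
        total = sum(r[2] for r in rows)
        if total > 0:
            for r in rows:
                r[2] = r[2] / total
        placements.append({"p": rows, "n": [read_id]})
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "placements": placements,
        "fields": ["edge_num", "likelihood", "like_weight_ratio",
                   "distal_length", "pendant_length"],
        "metadata": {"invocation": "lshplace"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
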