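"""Colored k-mer sets as a binary multitree guided by the reference phylogeny.

A *color* is a subset of reference genomes that share at least one k-mer.
Rather than storing each color extensionally, every non-singleton color is
the disjoint union of exactly two child colors, forming a binary multitree
(a DAG whose children are disjoint). The multitree is built jointly with
the k-mer index by a post-order traversal of the reference phylogeny: at
each internal node, k-mers shared between the children's k-mer sets get a
new (or reused) color that unions the two existing colors. Under a
perfect-character model of genome evolution every color coincides with a
clade of the phylogeny and no extra nodes are created; real shared k-mers
additionally create "meta-colors" for non-clade subsets.

Color union lookup uses Abelian-group hashing: every reference carries an
independent 128-bit key, a color's key is the sum of its members' keys mod
2^128, and a union's key is the sum of its children's keys. Key hits are
verified structurally so hash collisions can never merge distinct colors.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["ColorNode", "ColorMultitree", "assign_colors_postorder",
           "build_multitree_sequential", "multitree_stats"]

_KEY_MOD = 1 << 128


@dataclass
class ColorNode:
    id: int
    children: tuple[int, int] | None  # internal: two child color ids
    ref: str | None                   # singleton: reference id

    @property
    def is_singleton(self) -> bool:
        return self.ref is not None


class ColorMultitree:
    """Binary multitree of colors over a fixed reference set.

    Color ids index the node array; ids ``0..R-1`` are the singleton colors
    in the order of ``ref_ids``.
    """

    def __init__(self, ref_ids: Sequence[str], key_seed: int = 0):
        self.ref_ids = list(ref_ids)
        if len(set(self.ref_ids)) != len(self.ref_ids):
            raise ValueError("duplicate reference ids")
        self.key_seed = key_seed
        rng = np.random.default_rng(key_seed)
        halves = rng.integers(0, 1 << 62, size=(len(self.ref_ids), 3))
        self._ref_keys = [(int(a) | (int(b) << 62) | (int(c) << 124)) % _KEY_MOD
                          for a, b, c in halves]
        self.nodes: list[ColorNode] = [
            ColorNode(id=i, children=None, ref=r) for i, r in enumerate(self.ref_ids)
        ]
        self._keys: list[int] = [k % _KEY_MOD for k in self._ref_keys]
        self._by_key: dict[int, list[int]] = defaultdict(list)
        for i, k in enumerate(self._keys):
            self._by_key[k].append(i)
        self._resolved: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(len(self.ref_ids))
        }
        self.observed: dict[int, bool] = {}
        # clades of the guiding phylogeny (frozensets of singleton ids);
        # filled by assign_colors_postorder, used for height accounting
        self.clade_colors: set[int] = set(range(len(self.ref_ids)))

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_internal(self) -> int:
        return len(self.nodes) - len(self.ref_ids)

    def key(self, c: int) -> int:
        return self._keys[c]

    def _resolve_ids(self, c: int) -> frozenset[int]:
        if c not in self._resolved:
            node = self.nodes[c]
            a, b = node.children
            self._resolved[c] = self._resolve_ids(a) | self._resolve_ids(b)
        return self._resolved[c]

    def resolve(self, c: int) -> set[str]:
        """The set of reference ids a color stands for."""
        if not (0 <= c < len(self.nodes)):
            raise KeyError(f"unknown color id {c}")
        return {self.ref_ids[i] for i in self._resolve_ids(c)}

    def parent_color(self, c1: int, c2: int) -> int:
        """Color for the disjoint union of two colors; reuses an existing
        node when one structurally matches, else creates a new internal
        node with children (c1, c2). Commutative and idempotent."""
        s1, s2 = self._resolve_ids(c1), self._resolve_ids(c2)
        if s1 & s2:
            raise ValueError(
                f"children of a color must be disjoint; colors {c1} and {c2} "
                f"share {sorted(self.ref_ids[i] for i in s1 & s2)}")
        key = (self._keys[c1] + self._keys[c2]) % _KEY_MOD
        union = s1 | s2
        for cand in self._by_key.get(key, ()):
            # verify structurally: equal keys with different member sets must
            # never merge (hash-collision safety)
            if self._resolve_ids(cand) == union:
                return cand
        cid = len(self.nodes)
        lo, hi = (c1, c2) if c1 <= c2 else (c2, c1)
        self.nodes.append(ColorNode(id=cid, children=(lo, hi), ref=None))
        self._keys.append(key)
        self._by_key[key].append(cid)
        self._resolved[cid] = union
        return cid

    def mark_observed(self, colors: Iterable[int]) -> None:
        self.observed = {c: False for c in range(len(self.nodes))}
        for c in colors:
            self.observed[c] = True

    def height(self, c: int) -> int:
        """0 for singletons and colors equal to a clade of the guiding
        phylogeny; otherwise 1 + max height of the children."""
        if c in self.clade_colors or self.nodes[c].is_singleton:
            return 0
        a, b = self.nodes[c].children
        return 1 + max(self.height(a), self.height(b))

    def to_dict(self) -> dict:
        return {
            "ref_ids": self.ref_ids,
            "key_seed": self.key_seed,
            "children": [list(n.children) for n in self.nodes if n.children],
            "clade_colors": sorted(self.clade_colors),
            "observed": [c for c, f in self.observed.items() if f],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorMultitree":
        mt = cls(d["ref_ids"], key_seed=d["key_seed"])
        for c1, c2 in d["children"]:
            cid = len(mt.nodes)
            mt.nodes.append(ColorNode(id=cid, children=(c1, c2), ref=None))
            key = (mt._keys[c1] + mt._keys[c2]) % _KEY_MOD
            mt._keys.append(key)
            mt._by_key[key].append(cid)
            mt._resolve_ids(cid)
        mt.clade_colors = set(d["clade_colors"])
        mt.mark_observed(d["observed"])
        return mt


def assign_colors_postorder(
    tree, per_ref_kmers: Mapping[str, Iterable[int]], key_seed: int = 0
) -> tuple[dict[int, int], ColorMultitree]:
    """Joint color assignment by post-order traversal of the phylogeny.

    ``tree`` is a :class:`lshplace.placement.Phylogeny` whose leaves match
    the keys of ``per_ref_kmers`` (k-mer encoding values per reference).
    Returns the final k-mer -> color-id map and the multitree. Polytomies
    are resolved as a ladder in child order: children are merged into the
    running k-mer set one at a time.
    """
    leaf_labels = [leaf.label for leaf in tree.leaves]
    missing = set(leaf_labels) ^ set(per_ref_kmers)
    if missing:
        raise ValueError(f"tree leaves and references disagree: {sorted(missing)}")
    mt = ColorMultitree(leaf_labels, key_seed=key_seed)
    singleton = {r: i for i, r in enumerate(leaf_labels)}

    def _merge(acc: dict[int, int], other: dict[int, int]) -> dict[int, int]:
        if len(other) > len(acc):
            acc, other = other, acc
        for x, c2 in other.items():
            c1 = acc.get(x)
            acc[x] = c2 if c1 is None else mt.parent_color(c1, c2)
        return acc

    def _visit(node) -> dict[int, int]:
        if node.is_leaf:
            return {int(x): singleton[node.label] for x in per_ref_kmers[node.label]}
        acc: dict[int, int] = {}
        for child in node.children:
            acc = _merge(acc, _visit(child))
        return acc

    assignment = _visit(tree.root)
    mt.mark_observed(assignment.values())
    # colors whose member set is a whole clade of the phylogeny have height 0
    clade_sets = {frozenset(s) for s in tree.clade_leafsets().values()}
    mt.clade_colors = {
        c for c in range(len(mt.nodes))
        if frozenset(mt.resolve(c)) in clade_sets
    }
    return assignment, mt


def build_multitree_sequential(
    ref_ids: Sequence[str], color_sets: Iterable[frozenset[str]],
    seed: int = 0, key_seed: int = 0,
) -> ColorMultitree:
    """Phylogeny-free baseline: realize each observed color by folding its
    members together one by one in a random order. Used to quantify how much
    the phylogeny-guided construction saves."""
    rng = np.random.default_rng(seed)
    mt = ColorMultitree(ref_ids, key_seed=key_seed)
    singleton = {r: i for i, r in enumerate(ref_ids)}
    observed = []
    for cs in color_sets:
        members = sorted(cs)
        order = rng.permutation(len(members))
        c = singleton[members[order[0]]]
        for i in order[1:]:
            c = mt.parent_color(c, singleton[members[i]])
        observed.append(c)
    mt.mark_observed(observed)
    return mt


def multitree_stats(mt: ColorMultitree, assignment: Mapping[int, int] | None = None) -> dict:
    """Summary statistics: node counts, unobserved internal colors, and the
    per-k-mer height distribution (0 when the k-mer's color is a clade of
    the guiding phylogeny)."""
    n_nodes = len(mt.nodes)
    n_unobserved = sum(
        1 for n in mt.nodes
        if not n.is_singleton and not mt.observed.get(n.id, False)
    )
    heights = {}
    mean_h = 0.0
    if assignment:
        counts: dict[int, int] = defaultdict(int)
        for c in assignment.values():
            counts[mt.height(c)] += 1
        heights = dict(sorted(counts.items()))
        total = sum(heights.values())
        mean_h = sum(h * n for h, n in heights.items()) / total if total else 0.0
    return {
        "n_nodes": n_nodes,
        "n_singletons": len(mt.ref_ids),
        "n_internal": mt.n_internal,
        "n_unobserved": n_unobserved,
        "height_distribution": heights,
        "mean_height": mean_h,
    }
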