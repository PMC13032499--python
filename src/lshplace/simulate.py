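"""Synthetic genome evolution and read simulation with exact ground truth.

Genomes evolve from a base sequence by Jukes-Cantor substitutions (uniform
choice among the three alternative bases, no indels), with Gamma-distributed
rate heterogeneity across fixed-length regions standing in for genes: each
region draws a relative rate multiplier from Gamma(mean 1, variance 1/alpha)
once, and about 5% of regions are intergenic and mutation-free. Because
there are no indels, all genomes share coordinates with the base, so the
true Hamming distance of any read interval to any genome is exactly
recomputable from the stored mutation positions — the ground-truth contract
for every recovery test.

Reads are fixed-length, sampled uniformly from both strands; optional
uniform sequencing error is applied *after* the true distance is recorded,
so the recorded distance reflects evolutionary divergence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import revcomp
from .placement import Phylogeny, PhyloNode

__all__ = ["EvolvedGenome", "SimulatedRead", "RateMap", "make_rate_map",
           "random_genome", "evolve_genome", "simulate_reads",
           "simulate_reference_set"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RateMap:
    """Per-region relative rate multipliers shared across distance levels."""

    region_len: int
    rates: np.ndarray          # one multiplier per region; 0 for intergenic
    length: int

    def site_rates(self) -> np.ndarray:
        reps = np.repeat(self.rates, self.region_len)
        return reps[: self.length]


@dataclass
class EvolvedGenome:
    sequence: str
    mutated_positions: np.ndarray      # sorted 0-based positions that changed
    true_gnd: float                    # realized genome-wide nucleotide distance
    rate_map: RateMap

    def interval_distance(self, start: int, end: int) -> float:
        """Hamming distance to the base genome on [start, end), per base."""
        lo = np.searchsorted(self.mutated_positions, start)
        hi = np.searchsorted(self.mutated_positions, end)
        return float(hi - lo) / (end - start)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    genome: str
    start: int
    end: int
    strand: str                        # "+" or "-"
    true_distance: float               # vs the base genome on [start, end)


def make_rate_map(length: int, region_len: int = 1000, alpha_gamma: float = 5.0,
                  intergenic_frac: float = 0.05, seed: int = 0) -> RateMap:
    """Draw per-region Gamma(shape=alpha, scale=1/alpha) rate multipliers
    (mean 1, variance 1/alpha); a random ~5% of regions are intergenic with
    rate 0."""
    rng = np.random.default_rng(seed)
    n_regions = (length + region_len - 1) // region_len
    rates = rng.gamma(shape=alpha_gamma, scale=1.0 / alpha_gamma, size=n_regions)
    n_inter = int(round(intergenic_frac * n_regions))
    if n_inter:
        rates[rng.choice(n_regions, size=n_inter, replace=False)] = 0.0
    return RateMap(region_len=region_len, rates=rates, length=length)


def random_genome(length: int, seed: int = 0) -> str:
    """I.i.d. uniform ACGT sequence."""
    rng = np.random.default_rng(seed)
    return _to_seq(rng.integers(0, 4, size=length).astype(np.uint8))


def _mutate(codes: np.ndarray, positions: np.ndarray, rng) -> np.ndarray:
    """Jukes-Cantor substitution: each mutated site moves to one of the
    three other bases uniformly."""
    out = codes.copy()
    shift = rng.integers(1, 4, size=len(positions))
    out[positions] = (out[positions] + shift) % 4
    return out


def _to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode(), np.uint8)]
    if np.any(codes == 255):
        raise ValueError("base genome must be pure ACGT")
    return codes


def _to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def evolve_genome(base: str, target_D: float, alpha_gamma: float = 5.0,
                  region_len: int = 1000, seed: int = 0,
                  rate_map: RateMap | None = None) -> EvolvedGenome:
    """Evolve ``base`` to an expected genome-wide distance ``target_D``.

    Per-site substitution probabilities are proportional to the site's
    region rate, scaled so the expected mutation count is ``target_D *
    len(base)`` (intergenic regions absorb none). Deterministic under
    ``seed``; pass a shared ``rate_map`` to keep region rates identical
    across distance levels.
    """
    if not (0 <= target_D <= 0.3):
        raise ValueError("target_D must be in [0, 0.3]")
    n = len(base)
    if rate_map is None:
        rate_map = make_rate_map(n, region_len=region_len,
                                 alpha_gamma=alpha_gamma, seed=seed)
    rng = np.random.default_rng(seed + 1)
    codes = _to_codes(base)
    site_rates = rate_map.site_rates().astype(float)
    total_rate = site_rates.sum()
    if target_D > 0 and total_rate == 0:
        raise ValueError("rate map has no mutable sites")
    if target_D == 0:
        return EvolvedGenome(sequence=base,
                             mutated_positions=np.zeros(0, dtype=np.int64),
                             true_gnd=0.0, rate_map=rate_map)
    p_site = target_D * n * site_rates / total_rate
    if np.any(p_site > 1.0):
        if np.mean(p_site > 1.0) > 0.01:
            raise ValueError(
                f"target_D={target_D} is too high for this rate map")
        p_site = np.clip(p_site, 0.0, 1.0)
    hit = rng.random(n) < p_site
    positions = np.nonzero(hit)[0]
    mutated = _mutate(codes, positions, rng)
    return EvolvedGenome(sequence=_to_seq(mutated),
                         mutated_positions=positions.astype(np.int64),
                         true_gnd=len(positions) / n, rate_map=rate_map)


def simulate_reads(genome: EvolvedGenome | str, L: int = 150, n: int = 100,
                   error_rate: float = 0.0, seed: int = 0,
                   genome_id: str = "g") -> list[SimulatedRead]:
    """Sample ``n`` length-``L`` reads at uniform positions on both strands.

    ``true_distance`` counts evolutionary substitutions in the source
    interval only; sequencing errors (uniform per-base, applied afterwards)
    do not enter it.
    """
    if n <= 0:
        return []
    seq = genome.sequence if isinstance(genome, EvolvedGenome) else genome
    if len(seq) < L:
        raise ValueError(f"genome length {len(seq)} < read length {L}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(seq) - L + 1, size=n)
    strands = rng.random(n) < 0.5
    reads = []
    for i, (start, minus) in enumerate(zip(starts.tolist(), strands.tolist())):
        end = start + L
        frag = seq[start:end]
        if minus:
            frag = revcomp(frag)
        if isinstance(genome, EvolvedGenome):
            dist = genome.interval_distance(start, end)
        else:
            dist = 0.0
        if error_rate > 0:
            codes = _to_codes(frag)
            errs = np.nonzero(rng.random(L) < error_rate)[0]
            frag = _to_seq(_mutate(codes, errs, rng))
        reads.append(SimulatedRead(
            read_id=f"{genome_id}_read{i}", sequence=frag, genome=genome_id,
            start=int(start), end=int(end), strand="-" if minus else "+",
            true_distance=dist))
    return reads


def _random_topology(labels: list[str], rng) -> PhyloNode:
    """Random rooted binary topology by sequential random edge attachment."""
    nodes = [PhyloNode(0, None, None, labels[0]), PhyloNode(0, None, None, labels[1])]
    root = PhyloNode(0, None, None, None)
    for child in nodes:
        child.parent = root
        root.children.append(child)
    edges = list(nodes)  # nodes with a parent: attachable edges
    for label in labels[2:]:
        target = edges[rng.integers(0, len(edges))]
        new_leaf = PhyloNode(0, None, None, label)
        new_internal = PhyloNode(0, target.parent, None, None)
        target.parent.children[target.parent.children.index(target)] = new_internal
        target.parent = new_internal
        new_leaf.parent = new_internal
        new_internal.children = [target, new_leaf]
        edges.extend([new_leaf, new_internal])
    return root


def simulate_reference_set(
    n_refs: int, tree_shape_seed: int = 0, genome_len: int = 30_000,
    depth_scale: float = 0.05,
) -> tuple[Phylogeny, dict[str, EvolvedGenome], str]:
    """A random rooted binary tree with genomes evolved down it.

    Branch lengths are exponential with mean ``depth_scale`` (expected
    substitutions per site); an ancestral genome accumulates Jukes-Cantor
    substitutions independently along each branch. Returns the phylogeny,
    per-leaf :class:`EvolvedGenome` objects (mutation positions relative to
    the ancestor), and the ancestor sequence.
    """
    if n_refs < 2:
        raise ValueError("need at least 2 references")
    rng = np.random.default_rng(tree_shape_seed)
    labels = [f"R{i}" for i in range(n_refs)]
    root = _random_topology(labels, rng)
    tree = Phylogeny(root)
    for node in tree.nodes:
        if node.parent is not None:
            node.length = float(rng.exponential(depth_scale)) if depth_scale > 0 else 0.0
    ancestor = random_genome(genome_len, seed=int(rng.integers(0, 2**31)))
    anc_codes = _to_codes(ancestor)
    rate_map = RateMap(region_len=genome_len, rates=np.ones(1), length=genome_len)
    genomes: dict[str, EvolvedGenome] = {}

    def _descend(node: PhyloNode, codes: np.ndarray):
        if node.parent is not None and node.length and node.length > 0:
            p = min(node.length, 0.75)
            hit = rng.random(genome_len) < p
            codes = _mutate(codes, np.nonzero(hit)[0], rng)
        if node.is_leaf:
            changed = np.nonzero(codes != anc_codes)[0].astype(np.int64)
            genomes[node.label] = EvolvedGenome(
                sequence=_to_seq(codes), mutated_positions=changed,
                true_gnd=len(changed) / genome_len, rate_map=rate_map)
        else:
            for child in node.children:
                _descend(child, codes)

    _descend(tree.root, anc_codes.copy())
    return tree, genomes, ancestor
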