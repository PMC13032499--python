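"""The LSH k-mer index: build, serialize, and query with inexact matching.

Reference k-mers (canonical minimizers) are stored sorted by their
``(LSH bucket, payload)`` key, where the bucket is the 2h-bit hash over the
sampled positions and the payload is the remaining 2(k-h) bits. A parallel
array holds each k-mer's color id in the color multitree. Querying a k-mer
compares it, at exact Hamming distance, against only the k-mers in its own
bucket and keeps matches with HD <= delta; matches in other buckets are the
scheme's (modeled) false negatives. Bucket boundaries are recovered by
binary search over the sorted keys, which yields the same slices as a dense
offset array of size 2^(2h) without materializing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import encoding as enc
from .colors import ColorMultitree, assign_colors_postorder
from .distance import MatchHistogram, check_concavity, filter_distant_refs
from .encoding import EncodedKmer, EncodingParams

__all__ = ["QueryParams", "KmerMatch", "RefMeta", "LshIndex",
           "build_index", "build_index_batched", "build_index_from_seqs",
           "collect_read_matches", "query_kmer"]

_U = np.uint64
_PAIR_MASK = _U(0x5555555555555555)


@dataclass(frozen=True)
class QueryParams:
    """Query-time thresholds: max match HD (delta), placement match-count
    threshold (tau), and LRT significance level (alpha)."""

    delta: int = 4
    tau: int = 2
    alpha: float = 0.10

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.tau > self.delta:
            raise ValueError(f"tau ({self.tau}) must not exceed delta ({self.delta})")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"delta": self.delta, "tau": self.tau, "alpha": self.alpha}

    @classmethod
    def from_dict(cls, d: dict) -> "QueryParams":
        return cls(**d)


@dataclass(frozen=True)
class KmerMatch:
    color_id: int
    hd: int
    query_position: int | None = None


@dataclass(frozen=True)
class RefMeta:
    ref_id: str
    rho: float
    n_distinct: int
    n_minimizers: int


def _payload_hd(x: np.ndarray) -> np.ndarray:
    """Hamming distance from XORed 2-bit-group keys: OR each group's two
    bits together, then popcount."""
    return np.bitwise_count((x | (x >> _U(1))) & _PAIR_MASK)


class LshIndex:
    """Sorted k-mer key array + parallel color array + reference metadata."""

    def __init__(self, keys: np.ndarray, colors: np.ndarray,
                 params: EncodingParams, qparams: QueryParams,
                 ref_meta: dict[str, RefMeta], multitree: ColorMultitree):
        if len(keys) != len(colors):
            raise ValueError("keys and colors must be parallel arrays")
        if np.any(np.diff(keys.astype(np.uint64)) == 0):
            raise ValueError("duplicate keys in index")
        self.keys = np.ascontiguousarray(keys, dtype=np.uint64)
        self.colors = np.ascontiguousarray(colors, dtype=np.int64)
        self.params = params
        self.qparams = qparams
        self.ref_meta = ref_meta
        self.multitree = multitree
        self._payload_bits = 2 * (params.k - params.h)
        self._resolve_cache: dict[int, tuple[str, ...]] = {}

    def __len__(self) -> int:
        return len(self.keys)

    # -- bucket geometry ----------------------------------------------------

    def key_of(self, kmer: EncodedKmer) -> int:
        b = enc.lsh_value(kmer, self.params)
        return (b << self._payload_bits) | enc.payload_value(kmer, self.params)

    def bucket_slice(self, bucket: int) -> tuple[int, int]:
        lo = int(np.searchsorted(self.keys, _U(bucket << self._payload_bits)))
        hi = int(np.searchsorted(self.keys, _U((bucket + 1) << self._payload_bits)))
        return lo, hi

    def offset_index(self) -> np.ndarray:
        """Dense cumulative bucket-boundary array of length 2^(2h): entry i
        is the number of stored k-mers with bucket id <= i. Intended for
        small h; equivalent to the binary-search boundaries."""
        n_buckets = 1 << (2 * self.params.h)
        buckets = (self.keys >> _U(self._payload_bits)).astype(np.int64)
        counts = np.bincount(buckets, minlength=n_buckets)
        return np.cumsum(counts)

    def resolve_color(self, color_id: int) -> tuple[str, ...]:
        cached = self._resolve_cache.get(color_id)
        if cached is None:
            cached = tuple(sorted(self.multitree.resolve(color_id)))
            self._resolve_cache[color_id] = cached
        return cached

    # -- serialization ------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = {
            "format_version": 1,
            "params": self.params.to_dict(),
            "qparams": self.qparams.to_dict(),
            "ref_meta": {
                r: {"rho": m.rho, "n_distinct": m.n_distinct,
                    "n_minimizers": m.n_minimizers}
                for r, m in self.ref_meta.items()
            },
            "n_kmers": int(len(self.keys)),
            "multitree": self.multitree.to_dict(),
        }
        (out / "header.json").write_text(json.dumps(header, indent=1))
        np.save(out / "keys.npy", self.keys)
        np.save(out / "colors.npy", self.colors)

    @classmethod
    def load(cls, in_dir: str | Path) -> "LshIndex":
        src = Path(in_dir)
        header = json.loads((src / "header.json").read_text())
        params = EncodingParams.from_dict(header["params"])
        qparams = QueryParams.from_dict(header["qparams"])
        ref_meta = {
            r: RefMeta(ref_id=r, rho=m["rho"], n_distinct=m["n_distinct"],
                       n_minimizers=m["n_minimizers"])
            for r, m in header["ref_meta"].items()
        }
        multitree = ColorMultitree.from_dict(header["multitree"])
        keys = np.load(src / "keys.npy")
        colors = np.load(src / "colors.npy")
        return cls(keys, colors, params, qparams, ref_meta, multitree)


def _load_reference_seqs(references: Mapping[str, str | Path]) -> dict[str, list[str]]:
    from .io import read_fastx
    out: dict[str, list[str]] = {}
    for ref_id, path in references.items():
        out[ref_id] = [seq for _rid, seq, *_ in read_fastx(str(path))]
    return out


def _index_arrays(per_ref_kmers, tree, params, key_seed):
    assignment, multitree = assign_colors_postorder(
        tree, per_ref_kmers, key_seed=key_seed)
    values = np.fromiter(assignment.keys(), dtype=np.uint64, count=len(assignment))
    color_ids = np.fromiter(assignment.values(), dtype=np.int64, count=len(assignment))
    buckets = enc.lsh_values_vec(values, params)
    payloads = enc.payload_values_vec(values, params)
    keys = (buckets << _U(2 * (params.k - params.h))) | payloads
    order = np.argsort(keys, kind="stable")
    return keys[order], color_ids[order], multitree


def build_index_from_seqs(
    ref_seqs: Mapping[str, list[str] | str],
    tree,
    params: EncodingParams | None = None,
    qparams: QueryParams | None = None,
) -> LshIndex:
    """Build the index from in-memory reference sequences (one or more
    records per reference)."""
    params = params or EncodingParams()
    qparams = qparams or QueryParams()
    if (params.k, params.h, qparams.delta) != (29, 14, 4):
        check_concavity(params.k, params.h, qparams.delta)
    per_ref_kmers: dict[str, np.ndarray] = {}
    ref_meta: dict[str, RefMeta] = {}
    for ref_id, seqs in ref_seqs.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        minim: list[np.ndarray] = []
        distinct: list[np.ndarray] = []
        for seq in seqs:
            _pos, vals = enc.minimizer_positions(seq, params)
            minim.append(vals)
            distinct.append(enc.distinct_canonical_kmers(seq, params))
        mvals = np.unique(np.concatenate(minim)) if minim else np.zeros(0, np.uint64)
        dvals = np.unique(np.concatenate(distinct)) if distinct else np.zeros(0, np.uint64)
        if len(mvals) == 0:
            raise ValueError(f"reference {ref_id!r} produced no indexed k-mers "
                             f"(empty or shorter than the window length)")
        per_ref_kmers[ref_id] = mvals
        ref_meta[ref_id] = RefMeta(
            ref_id=ref_id, rho=len(mvals) / len(dvals),
            n_distinct=int(len(dvals)), n_minimizers=int(len(mvals)))
    keys, color_ids, multitree = _index_arrays(
        per_ref_kmers, tree, params, key_seed=params.seed)
    return LshIndex(keys, color_ids, params, qparams, ref_meta, multitree)


def build_index(
    references: Mapping[str, str | Path],
    tree,
    params: EncodingParams | None = None,
    qparams: QueryParams | None = None,
) -> LshIndex:
    """Build the index from reference FASTA files keyed by reference id.

    Tree leaf labels must match the reference ids exactly.
    """
    return build_index_from_seqs(_load_reference_seqs(references), tree,
                                 params, qparams)


def build_index_batched(
    references: Mapping[str, str | Path],
    tree,
    params: EncodingParams | None = None,
    qparams: QueryParams | None = None,
    n_batches: int = 1,
    from_seqs: Mapping[str, list[str] | str] | None = None,
) -> LshIndex:
    """Build the index in bucket-partitioned batches and merge.

    Batch ``b`` handles only k-mers whose bucket id is congruent to ``b``
    modulo ``n_batches`` (capping peak per-batch memory); the merged result
    is identical, entry for entry, to the unbatched build. ``n_batches``
    larger than the number of buckets simply yields empty batches.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    full = (build_index_from_seqs(from_seqs, tree, params, qparams)
            if from_seqs is not None
            else build_index(references, tree, params, qparams))
    if n_batches == 1:
        return full
    params, qparams = full.params, full.qparams
    shift = _U(2 * (params.k - params.h))
    batch_keys, batch_colors = [], []
    for b in range(n_batches):
        mask = (full.keys >> shift) % _U(n_batches) == _U(b)
        batch_keys.append(full.keys[mask])
        batch_colors.append(full.colors[mask])
    keys = np.concatenate(batch_keys)
    colors = np.concatenate(batch_colors)
    order = np.argsort(keys, kind="stable")
    return LshIndex(keys[order], colors[order], params, qparams,
                    full.ref_meta, full.multitree)


def query_kmer(index: LshIndex, kmer: EncodedKmer,
               query_position: int | None = None) -> list[KmerMatch]:
    """All stored k-mers in the query's LSH bucket within HD <= delta."""
    bucket = enc.lsh_value(kmer, index.params)
    qkey = _U(index.key_of(kmer))
    lo, hi = index.bucket_slice(bucket)
    if lo == hi:
        return []
    x = index.keys[lo:hi] ^ qkey
    hd = _payload_hd(x)
    mask = hd <= index.qparams.delta
    return [
        KmerMatch(color_id=int(c), hd=int(d), query_position=query_position)
        for c, d in zip(index.colors[lo:hi][mask], hd[mask])
    ]


def collect_read_matches(
    index: LshIndex, read: str, filter_distant: bool = True,
    distant_gap: int = 2,
) -> dict[str, MatchHistogram]:
    """Per-reference match histograms for one read.

    Every one of the read's ``L - k + 1`` k-mer positions is a trial; for
    each position and reference only the minimum-HD match is kept. Positions
    whose window contains a non-ACGT base count as misses. References whose
    best observed HD exceeds the overall best by more than ``distant_gap``
    are dropped (distant-genome prefilter), unless ``filter_distant`` is
    off.
    """
    params, delta = index.params, index.qparams.delta
    k = params.k
    L = len(read)
    trials = L - k + 1
    if trials < 1:
        return {}
    codes = enc.seq_codes(read)
    canon, valid, _ = enc.kmer_values(codes, k)
    shift = _U(2 * (k - params.h))
    idx_valid = np.nonzero(valid)[0]
    if len(idx_valid) == 0:
        return {}
    vals = canon[idx_valid]
    buckets = enc.lsh_values_vec(vals, params)
    payloads = enc.payload_values_vec(vals, params)
    qkeys = (buckets << shift) | payloads
    los = np.searchsorted(index.keys, buckets << shift)
    his = np.searchsorted(index.keys, (buckets + _U(1)) << shift)
    ref_best: dict[str, np.ndarray] = {}
    for j in range(len(idx_valid)):
        lo, hi = int(los[j]), int(his[j])
        if lo == hi:
            continue
        x = index.keys[lo:hi] ^ qkeys[j]
        hd = _payload_hd(x)
        mask = hd <= delta
        if not np.any(mask):
            continue
        pos_best: dict[str, int] = {}
        for c, d in zip(index.colors[lo:hi][mask], hd[mask]):
            d = int(d)
            for ref in index.resolve_color(int(c)):
                prev = pos_best.get(ref)
                if prev is None or d < prev:
                    pos_best[ref] = d
        for ref, d in pos_best.items():
            arr = ref_best.get(ref)
            if arr is None:
                arr = np.zeros(delta + 1, dtype=np.int64)
                ref_best[ref] = arr
            arr[d] += 1
    hists = {
        ref: MatchHistogram(
            v=v.astype(float), u=float(trials - v.sum()),
            rho=index.ref_meta[ref].rho, L=L, k=k)
        for ref, v in ref_best.items()
    }
    if filter_distant:
        hists = filter_distant_refs(hists, gap=distant_gap)
    return hists
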