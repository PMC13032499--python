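"""k-mer encoding, Hamming distance, minimizer selection, and LSH values.

A k-mer over {A,C,G,T} is packed into two bit channels (the "left/right"
split encoding): for each position the 2-bit base code ``A=00, C=01, G=10,
T=11`` contributes its high bit to the left channel and its low bit to the
right channel. The Hamming distance between two encoded k-mers is then
``popcount((l1 ^ l2) | (r1 ^ r2))`` -- four bit-parallel instructions, no
per-character loop.

The locality-sensitive hash of a k-mer is the concatenation of its 2-bit
codes at ``h`` fixed, randomly chosen positions, giving a ``2h``-bit bucket
id; two k-mers at Hamming distance ``d`` collide with probability
``C(k-h, d) / C(k, d)``.

Minimizers subsample reference k-mers: within every window of ``w``
consecutive bases, the canonical k-mer whose encoding has the smallest
MurmurHash3 finalizer value is retained (leftmost occurrence on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncodingParams",
    "EncodedKmer",
    "MinimizerRecord",
    "encode_kmer",
    "decode_kmer",
    "hamming",
    "canonicalize",
    "revcomp",
    "select_minimizers",
    "minimizer_positions",
    "lsh_value",
    "payload_value",
    "kmer_from_bucket_payload",
    "fmix64",
]

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> 2-bit code lookup; 255 marks non-ACGT
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _BYTE_CODE[ord(_b)] = _c
    _BYTE_CODE[ord(_b.lower())] = _c

_U = np.uint64
_MASK64 = (1 << 64) - 1


def fmix64(x: int, seed: int = 0) -> int:
    """MurmurHash3 64-bit finalizer of ``x`` mixed with ``seed``."""
    x = (x ^ seed) & _MASK64
    x ^= x >> 33
    x = (x * 0xFF51AFD7ED558CCD) & _MASK64
    x ^= x >> 33
    x = (x * 0xC4CEB9FE1A85EC53) & _MASK64
    x ^= x >> 33
    return x


def _fmix64_vec(x: np.ndarray, seed: int = 0) -> np.ndarray:
    x = x.astype(np.uint64) ^ _U(seed & _MASK64)
    x ^= x >> _U(33)
    x *= _U(0xFF51AFD7ED558CCD)
    x ^= x >> _U(33)
    x *= _U(0xC4CEB9FE1A85EC53)
    x ^= x >> _U(33)
    return x


@dataclass(frozen=True)
class EncodingParams:
    """Parameters of the k-mer encoding, minimizer and LSH schemes.

    k : k-mer length (bases).
    w : minimizer window length (bases), w >= k.
    h : number of LSH-sampled positions, h < k.
    seed : fixes the sampled positions and the minimizer hash.
    lsh_positions : the h sampled position indices in [0, k), sorted;
        derived deterministically from ``seed`` when not given.
    """

    k: int = 29
    w: int = 35
    h: int = 14
    seed: int = 1
    lsh_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (0 < self.h <= self.k):
            raise ValueError(f"need 0 < h <= k, got h={self.h}, k={self.k}")
        if self.w < self.k:
            raise ValueError(f"need w >= k, got w={self.w}, k={self.k}")
        if self.lsh_positions is None:
            rng = np.random.default_rng(self.seed)
            pos = tuple(sorted(rng.choice(self.k, size=self.h, replace=False).tolist()))
            object.__setattr__(self, "lsh_positions", pos)
        else:
            pos = tuple(sorted(int(p) for p in self.lsh_positions))
            if len(set(pos)) != self.h or any(p < 0 or p >= self.k for p in pos):
                raise ValueError("lsh_positions must be h distinct indices in [0, k)")
            object.__setattr__(self, "lsh_positions", pos)

    @property
    def payload_positions(self) -> tuple[int, ...]:
        """The k-h positions not sampled by the LSH, in order."""
        sampled = set(self.lsh_positions)
        return tuple(p for p in range(self.k) if p not in sampled)

    @property
    def hash_seed(self) -> int:
        # scalar mix of the user seed, shared by scalar and vector paths
        return fmix64(0x9E3779B97F4A7C15, self.seed & _MASK64)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "w": self.w,
            "h": self.h,
            "seed": self.seed,
            "lsh_positions": list(self.lsh_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingParams":
        return cls(
            k=d["k"], w=d["w"], h=d["h"], seed=d["seed"],
            lsh_positions=tuple(d["lsh_positions"]),
        )


@dataclass(frozen=True)
class EncodedKmer:
    """A k-mer packed as two bit channels (high bits, low bits)."""

    left_bits: int
    right_bits: int
    k: int

    @property
    def value(self) -> int:
        """The 2k-bit integer encoding: left channel above the right channel."""
        return (self.left_bits << self.k) | self.right_bits

    def code_at(self, pos: int) -> int:
        """2-bit base code at position ``pos`` (0-based from the 5' end)."""
        shift = self.k - 1 - pos
        return (((self.left_bits >> shift) & 1) << 1) | ((self.right_bits >> shift) & 1)


@dataclass(frozen=True)
class MinimizerRecord:
    kmer: EncodedKmer
    position: int
    source: str = ""


class InvalidKmerError(ValueError):
    pass


def encode_kmer(kmer: str) -> EncodedKmer:
    """Pack an ACGT string into the split bit encoding."""
    left = 0
    right = 0
    for ch in kmer:
        code = _CODE.get(ch.upper())
        if code is None:
            raise InvalidKmerError(f"non-ACGT character {ch!r} in k-mer")
        left = (left << 1) | (code >> 1)
        right = (right << 1) | (code & 1)
    return EncodedKmer(left, right, len(kmer))


def decode_kmer(ek: EncodedKmer) -> str:
    return "".join(_BASES[ek.code_at(j)] for j in range(ek.k))


def hamming(a: EncodedKmer, b: EncodedKmer) -> int:
    """Character-level Hamming distance via the bit-parallel channel trick."""
    if a.k != b.k:
        raise ValueError(f"k-mer length mismatch: {a.k} vs {b.k}")
    return (((a.left_bits ^ b.left_bits) | (a.right_bits ^ b.right_bits))).bit_count()


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encoded_revcomp(ek: EncodedKmer) -> EncodedKmer:
    # complement = XOR both channel bits with 1 (A<->T, C<->G), then reverse order
    mask = (1 << ek.k) - 1
    left = (~ek.left_bits) & mask
    right = (~ek.right_bits) & mask
    rl = rr = 0
    for _ in range(ek.k):
        rl = (rl << 1) | (left & 1)
        rr = (rr << 1) | (right & 1)
        left >>= 1
        right >>= 1
    return EncodedKmer(rl, rr, ek.k)


def canonicalize(kmer: str) -> str:
    """The strand-canonical form: whichever of the k-mer and its reverse
    complement has the numerically smaller encoding."""
    ek = encode_kmer(kmer)
    rc = _encoded_revcomp(ek)
    return kmer.upper() if ek.value <= rc.value else decode_kmer(rc)


def canonical_encoded(kmer: str) -> EncodedKmer:
    ek = encode_kmer(kmer)
    rc = _encoded_revcomp(ek)
    return ek if ek.value <= rc.value else rc


def lsh_value(kmer: EncodedKmer, params: EncodingParams) -> int:
    """2h-bit bucket id: concatenated 2-bit codes at the sampled positions."""
    v = 0
    for p in params.lsh_positions:
        v = (v << 2) | kmer.code_at(p)
    return v


def payload_value(kmer: EncodedKmer, params: EncodingParams) -> int:
    """2(k-h)-bit payload: concatenated codes at the non-sampled positions."""
    v = 0
    for p in params.payload_positions:
        v = (v << 2) | kmer.code_at(p)
    return v


def kmer_from_bucket_payload(bucket: int, payload: int, params: EncodingParams) -> EncodedKmer:
    """Reconstruct the full k-mer from its bucket id and stored payload."""
    codes = [0] * params.k
    for i, p in enumerate(reversed(params.lsh_positions)):
        codes[p] = (bucket >> (2 * i)) & 3
    for i, p in enumerate(reversed(params.payload_positions)):
        codes[p] = (payload >> (2 * i)) & 3
    left = right = 0
    for c in codes:
        left = (left << 1) | (c >> 1)
        right = (right << 1) | (c & 1)
    return EncodedKmer(left, right, params.k)


# ---------------------------------------------------------------------------
# vectorized bulk path
# ---------------------------------------------------------------------------

def seq_codes(seq: str) -> np.ndarray:
    """Byte array of 2-bit codes; 255 marks non-ACGT characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BYTE_CODE[raw]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical encoding values of all k-mers of a code array.

    Returns ``(canon, valid, is_rc)`` where ``canon[i]`` is the canonical
    (min of forward/reverse-complement) 2k-bit encoding value of the k-mer
    starting at ``i``, ``valid[i]`` is False when the window contains a
    non-ACGT base, and ``is_rc[i]`` marks k-mers whose canonical form is the
    reverse complement.
    """
    n = len(codes) - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)
    invalid = (codes == 255)
    safe = np.where(invalid, 0, codes)
    high = (safe >> 1).astype(np.uint64)
    low = (safe & 1).astype(np.uint64)
    one = _U(1)
    lf = np.zeros(n, dtype=np.uint64)
    rt = np.zeros(n, dtype=np.uint64)
    rl = np.zeros(n, dtype=np.uint64)
    rr = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        lf = (lf << one) | high[j:j + n]
        rt = (rt << one) | low[j:j + n]
        # reverse complement reads source position i + (k-1-j) for output slot j
        m = k - 1 - j
        rl = (rl << one) | (one - high[m:m + n])
        rr = (rr << one) | (one - low[m:m + n])
    ku = _U(k)
    fwd = (lf << ku) | rt
    rc = (rl << ku) | rr
    canon = np.minimum(fwd, rc)
    is_rc = rc < fwd
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") > 0
    return canon, ~bad, is_rc


def _codes_from_values(values: np.ndarray, k: int) -> np.ndarray:
    """(n, k) array of 2-bit codes from split-channel encoding values."""
    left = values >> _U(k)
    right = values & _U((1 << k) - 1)
    out = np.empty((len(values), k), dtype=np.uint8)
    for j in range(k):
        s = _U(k - 1 - j)
        out[:, j] = ((((left >> s) & _U(1)) << _U(1)) | ((right >> s) & _U(1))).astype(np.uint8)
    return out


def lsh_values_vec(values: np.ndarray, params: EncodingParams) -> np.ndarray:
    """Bucket ids for an array of encoding values."""
    codes = _codes_from_values(values, params.k)
    v = np.zeros(len(values), dtype=np.uint64)
    for p in params.lsh_positions:
        v = (v << _U(2)) | codes[:, p].astype(np.uint64)
    return v


def payload_values_vec(values: np.ndarray, params: EncodingParams) -> np.ndarray:
    codes = _codes_from_values(values, params.k)
    v = np.zeros(len(values), dtype=np.uint64)
    for p in params.payload_positions:
        v = (v << _U(2)) | codes[:, p].astype(np.uint64)
    return v


def minimizer_positions(seq: str, params: EncodingParams) -> tuple[np.ndarray, np.ndarray]:
    """Selected minimizer occurrences of a sequence.

    Returns ``(positions, values)``: sorted distinct 0-based start positions
    of the selected canonical k-mers and their encoding values. Every window
    of ``w`` bases consisting solely of ACGT characters contributes the
    k-mer with the smallest hash among its ``w - k + 1`` canonical k-mers
    (leftmost on ties); consecutive windows selecting the same occurrence
    are reported once.
    """
    k, w = params.k, params.w
    if len(seq) < w:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint64)
    codes = seq_codes(seq)
    canon, valid, _ = kmer_values(codes, k)
    hashes = _fmix64_vec(canon, params.hash_seed)
    hashes[~valid] = np.iinfo(np.uint64).max
    span = w - k + 1  # k-mers per window
    n_win = len(canon) - span + 1
    windows = np.lib.stride_tricks.sliding_window_view(hashes, span)
    arg = np.argmin(windows, axis=1)  # leftmost min per window
    # a window is usable only if all its k-mers are valid
    win_ok = np.convolve((~valid).astype(np.int32), np.ones(span, dtype=np.int32),
                         mode="valid") == 0
    sel = (np.arange(n_win, dtype=np.int64) + arg)[win_ok]
    positions = np.unique(sel)
    return positions, canon[positions]


def select_minimizers(seq: str, params: EncodingParams, source: str = "") -> list[MinimizerRecord]:
    positions, values = minimizer_positions(seq, params)
    k = params.k
    recs = []
    for pos, val in zip(positions.tolist(), values.tolist()):
        ek = EncodedKmer(int(val) >> k, int(val) & ((1 << k) - 1), k)
        recs.append(MinimizerRecord(kmer=ek, position=pos, source=source))
    return recs


def distinct_canonical_kmers(seq: str, params: EncodingParams) -> np.ndarray:
    """Sorted distinct canonical k-mer encoding values of a sequence."""
    codes = seq_codes(seq)
    canon, valid, _ = kmer_values(codes, params.k)
    return np.unique(canon[valid])
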