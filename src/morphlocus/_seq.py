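"""Low-level nucleotide encodings and packed k-mer machinery.

Sequences are held as ``uint8`` arrays with A,C,G,T -> 0,1,2,3 and 4 for any
other symbol (N and friends).  k-mers with k <= 31 are packed 2 bits per base
into ``uint64`` codes, which makes canonicalization, set operations and exact
matching plain integer-array work.  For 31 < k <= 63 a slow string-based
fallback is provided (the packed path cannot hold more than 31 bases).
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT_STR = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A,C,G,T -> 0..3, else 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGTN string."""
    return _DECODE[np.minimum(arr, 4)].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (invalid bases stay invalid)."""
    out = arr[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]


def _check_k(k: int) -> None:
    if not (1 <= k <= 31):
        raise ValueError(f"packed k-mer path requires 1 <= k <= 31, got {k}")


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def _rev64(v: np.ndarray) -> np.ndarray:
    """Reverse the 32 2-bit groups of each uint64 (mask-shift + byteswap)."""
    v = ((v >> np.uint64(2)) & _M2) | ((v & _M2) << np.uint64(2))
    v = ((v >> np.uint64(4)) & _M4) | ((v & _M4) << np.uint64(4))
    return v.byteswap()


def rc_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement codes from forward codes (complement each base,
    reverse base order)."""
    _check_k(k)
    mask = np.uint64((1 << (2 * k)) - 1)
    return _rev64(codes ^ mask) >> np.uint64(64 - 2 * k)


def _sliding_codes_flat(a: np.ndarray, k: int) -> np.ndarray:
    """Forward codes of all windows of a flat base array via 2-bit packing.

    Bases are packed 32 per uint64 word (first base in the top bits); each
    window's code is assembled from two adjacent words, so cost per window
    is constant rather than O(k).
    """
    n = len(a)
    V = n - k + 1
    if V <= 0:
        return np.zeros(0, dtype=np.uint64)
    n_words = (n + 31) // 32 + 1  # one spare word so q+1 is always valid
    padded = np.zeros(n_words * 32, dtype=np.uint64)
    padded[:n] = a & np.uint8(3)
    w = np.zeros(n_words, dtype=np.uint64)
    two = np.uint64(2)
    cols = padded.reshape(n_words, 32)
    for j in range(32):
        np.left_shift(w, two, out=w)
        np.bitwise_or(w, cols[:, j], out=w)
    # one pass per within-word offset: scalar shifts, contiguous word slices
    out = np.empty(V, dtype=np.uint64)
    drop = np.uint64(64 - 2 * k)
    for o in range(32):
        m = (V - 1 - o) // 32 + 1 if o < V else 0
        if m <= 0:
            continue
        if o == 0:
            out[0::32] = w[:m] >> drop
        else:
            s = np.uint64(2 * o)
            out[o::32] = ((w[:m] << s) | (w[1 : m + 1] >> (np.uint64(64) - s))) >> drop
    return out


def forward_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed forward-strand codes for every window along the last axis.

    ``arr`` may be 1-D (a sequence) or 2-D (a matrix of equal-length reads);
    the result has one code per window, shape ``arr.shape[:-1] + (L-k+1,)``.
    Windows containing invalid bases get arbitrary codes; use
    :func:`valid_windows` to mask them.
    """
    _check_k(k)
    arr = np.asarray(arr, dtype=np.uint8)
    L = arr.shape[-1]
    if L < k:
        return np.zeros(arr.shape[:-1] + (0,), dtype=np.uint64)
    V = L - k + 1
    if arr.ndim == 1:
        return _sliding_codes_flat(arr, k)
    if arr.ndim != 2:
        raise ValueError("expected a 1-D sequence or 2-D read matrix")
    flat = _sliding_codes_flat(np.ascontiguousarray(arr).reshape(-1), k)
    n = arr.shape[0]
    gather = (np.arange(n, dtype=np.int64)[:, None] * L + np.arange(V, dtype=np.int64)[None, :])
    return flat[gather]


def rc_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complement of every window (same layout
    as :func:`forward_codes`)."""
    return rc_from_codes(forward_codes(arr, k), k)


def valid_windows(arr: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of windows free of non-ACGT bases."""
    L = arr.shape[-1]
    if L < k:
        return np.zeros(arr.shape[:-1] + (0,), dtype=bool)
    bad = (arr > 3).astype(np.int32)
    cs = np.cumsum(bad, axis=-1)
    pad = np.zeros(arr.shape[:-1] + (1,), dtype=np.int32)
    cs = np.concatenate([pad, cs], axis=-1)
    return (cs[..., k:] - cs[..., :-k]) == 0


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of forward / reverse-complement) codes per window.

    Returns ``(codes, is_fwd)`` where ``is_fwd`` marks windows whose forward
    orientation is the canonical one.  Odd k guarantees no self-palindromes,
    so ties cannot occur for odd k.
    """
    f = forward_codes(arr, k)
    r = rc_from_codes(f, k)
    is_fwd = f <= r
    return np.minimum(f, r), is_fwd


def code_to_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    c = int(code)
    for j in range(k - 1, -1, -1):
        out[j] = b"ACGT"[c & 3]
        c >>= 2
    return out.decode("ascii")


def kmer_to_code(kmer: str) -> int:
    arr = encode(kmer)
    if (arr > 3).any():
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer}")
    c = 0
    for b in arr:
        c = (c << 2) | int(b)
    return c


def canonical_kmer(kmer: str) -> str:
    """Canonical form of a k-mer string (lexicographic min with its
    reverse complement); works for any k."""
    rc = revcomp_str(kmer.upper())
    fwd = kmer.upper()
    return fwd if fwd <= rc else rc


def random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform-base random encoded sequence of length n."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)
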