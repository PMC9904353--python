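"""Two-bit packing of DNA and vectorised k-mer window codes.

Internal numeric layer: sequences are mapped to uint8 codes (A=0, C=1, G=2,
T=3, anything else 4), concatenated with sentinel separators, and windows are
packed into one or two uint64 words.  Because the code order matches ASCII
order (A<C<G<T), integer order on packed words equals lexicographic order on
the strings, which is what canonical-k-mer selection needs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

SENTINEL = 4

_CODE = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def encode_concat(seqs: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences with one sentinel byte between them.

    Returns (codes, starts) where ``starts[i]`` is the offset of sequence i
    in the concatenated code array.  ``starts`` has one extra trailing entry
    (total length + 1) so that read lookup can use searchsorted directly.
    """
    blob = b"\xff".join(s.encode("ascii") if isinstance(s, str) else s for s in seqs)
    codes = _CODE[np.frombuffer(blob, dtype=np.uint8)]
    lengths = np.fromiter(
        (len(s) for s in seqs), dtype=np.int64
    ) if isinstance(seqs, (list, tuple)) else None
    if lengths is None:
        raise TypeError("encode_concat requires a list or tuple of sequences")
    starts = np.zeros(lengths.size + 1, dtype=np.int64)
    np.cumsum(lengths + 1, out=starts[1:])
    return codes, starts


def _pack_word(codes: np.ndarray, k: int, n: int) -> np.ndarray:
    """Pack k consecutive codes (k <= 32) into a uint64 per window start.

    Uses a doubling scheme: a word for 2m consecutive bases is built from
    two m-base words, so only O(log k) full-array passes are needed.
    """
    c = np.where(codes < SENTINEL, codes, 0).astype(np.uint64)
    # powers of two appearing in k's binary decomposition must be retained
    needed = {1 << b for b in range(k.bit_length()) if k & (1 << b)}
    # words[m][i] = packed value of m consecutive bases starting at i
    words = {1: c}
    m = 1
    while 2 * m <= k:
        w = words[m]
        nw = w[: w.size - m].copy()
        nw <<= np.uint64(2 * m)
        nw |= w[m:]
        words[2 * m] = nw
        if m not in needed:
            del words[m]
        m *= 2
    # combine powers of two by the binary decomposition of k
    result = None
    covered = 0
    for m in sorted(words, reverse=True):
        if covered + m <= k:
            part = words[m]
            if result is None:
                result = part[: codes.size - k + 1].copy()
            else:
                result <<= np.uint64(2 * m)
                result |= part[covered : covered + codes.size - k + 1]
            covered += m
        if covered == k:
            break
    return result[:n]


def window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of window starts whose k bases are all A/C/G/T."""
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = np.zeros(codes.size + 1, dtype=np.int64)
    np.cumsum(codes >= SENTINEL, out=bad[1:])
    return (bad[k:] - bad[:-k]) == 0


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Packed forward window words for every start position.

    Returns (hi, lo, valid).  For k <= 32 the word is in ``lo`` and ``hi`` is
    zero; for 32 < k <= 64 the first k-32 bases are in ``hi`` and the last 32
    in ``lo``, so (hi, lo) compares lexicographically.  A single 32-base pack
    feeds both words: the hi word of the window at i is the top k-32 bases
    of the 32-base word at i, and the lo word is the 32-base word at i+k-32.
    """
    if k > 64:
        raise ValueError("packed window codes support k <= 64")
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z, np.zeros(0, dtype=bool)
    valid = window_valid(codes, k)
    if k <= 32:
        lo = _pack_word(codes, k, n)
        hi = np.zeros(n, dtype=np.uint64)
    else:
        h = k - 32
        w32 = _pack_word(codes, 32, codes.size - 32 + 1)
        hi = w32[:n] >> np.uint64(2 * (32 - h))
        lo = np.ascontiguousarray(w32[h : h + n])
    return hi, lo, valid


def rc_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array; sentinels stay sentinels."""
    out = np.where(codes < SENTINEL, 3 - codes, SENTINEL).astype(np.uint8)
    return out[::-1]


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def _revcomp_words(w: np.ndarray, bases: int) -> np.ndarray:
    """Reverse-complement packed words in place-free vectorised bit ops.

    Complements every 2-bit base (bitwise NOT) and reverses base order:
    2-bit swap within nibbles, nibble swap within bytes, then a byteswap.
    The result is right-aligned for a ``bases``-base word.
    """
    x = ~w
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * bases)


def canonical_window_codes(
    codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (min of forward / reverse-complement) window words."""
    fhi, flo, valid = window_codes(codes, k)
    if k <= 32:
        rlo = _revcomp_words(flo, k)
        use_rc = rlo < flo
        lo = np.where(use_rc, rlo, flo)
        return fhi, lo, valid
    h = k - 32
    ra = _revcomp_words(flo, 32)  # rc of the window's last 32 bases
    rb = _revcomp_words(fhi, h)  # rc of the first h bases, right-aligned
    rhi = ra >> np.uint64(2 * (32 - h))
    rlo = ((ra & np.uint64((1 << (2 * (32 - h))) - 1)) << np.uint64(2 * h)) | rb
    use_rc = (rhi < fhi) | ((rhi == fhi) & (rlo < flo))
    hi = np.where(use_rc, rhi, fhi)
    lo = np.where(use_rc, rlo, flo)
    return hi, lo, valid


def pack_kmer(kmer: str, k: int) -> tuple[int, int]:
    """Pack a single k-mer string into (hi, lo) words."""
    codes = encode(kmer)
    if codes.size != k or (codes >= SENTINEL).any():
        raise ValueError(f"not a clean {k}-mer: {kmer!r}")
    hi, lo, _ = window_codes(codes, k)
    return int(hi[0]), int(lo[0])


def unpack_kmer(hi: int, lo: int, k: int) -> str:
    """Inverse of :func:`pack_kmer`."""
    out = np.empty(k, dtype=np.uint8)
    nlo = min(k, 32)
    v = int(lo)
    for j in range(nlo):
        out[k - 1 - j] = (v >> (2 * j)) & 3
    v = int(hi)
    for j in range(k - 32):
        out[k - 32 - 1 - j] = (v >> (2 * j)) & 3
    return decode(out)


def sort_word_pairs(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Order that sorts (hi, lo) pairs lexicographically (not stable).

    When ``hi`` fits in 36 bits (k <= 50) the pair is sorted with two plain
    argsorts over packed 64-bit keys, which is markedly faster than
    ``np.lexsort``'s stable mergesorts on large arrays.
    """
    if hi.size == 0:
        return np.zeros(0, dtype=np.int64)
    mask36 = np.uint64((1 << 36) - 1)
    if hi.size < (1 << 27) and int(hi.max()) < (1 << 36):
        key1 = (hi << np.uint64(28)) | (lo >> np.uint64(36))
        order = np.argsort(key1)
        k1s = key1[order]
        run_start = np.empty(k1s.size, dtype=np.uint64)
        run_start[0] = 0
        np.cumsum(k1s[1:] != k1s[:-1], dtype=np.uint64, out=run_start[1:])
        key2 = (run_start << np.uint64(36)) | (lo[order] & mask36)
        return order[np.argsort(key2)]
    return np.lexsort((lo, hi))


def aggregate_counts(
    hi: np.ndarray, lo: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort packed words and collapse duplicates; returns (hi, lo, counts)."""
    if hi.size == 0:
        return hi, lo, np.zeros(0, dtype=np.int64)
    order = sort_word_pairs(hi, lo)
    hi = hi[order]
    lo = lo[order]
    change = np.empty(hi.size, dtype=bool)
    change[0] = True
    np.not_equal(hi[1:], hi[:-1], out=change[1:])
    change[1:] |= lo[1:] != lo[:-1]
    idx = np.flatnonzero(change)
    counts = np.diff(np.append(idx, hi.size)).astype(np.int64)
    return hi[idx], lo[idx], counts


def merge_counts(
    parts: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge several (hi, lo, counts) triples into one sorted triple."""
    hi = np.concatenate([p[0] for p in parts])
    lo = np.concatenate([p[1] for p in parts])
    ct = np.concatenate([p[2] for p in parts])
    order = sort_word_pairs(hi, lo)
    hi, lo, ct = hi[order], lo[order], ct[order]
    change = np.empty(hi.size, dtype=bool)
    if hi.size:
        change[0] = True
        np.not_equal(hi[1:], hi[:-1], out=change[1:])
        change[1:] |= lo[1:] != lo[:-1]
    idx = np.flatnonzero(change)
    sums = np.add.reduceat(ct, idx) if idx.size else np.zeros(0, dtype=np.int64)
    return hi[idx], lo[idx], sums
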