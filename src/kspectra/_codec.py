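"""2-bit nucleotide codec and vectorised canonical k-mer codes.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, boundaries) becomes the
sentinel 255 and invalidates every window that covers it. A k-mer is packed
into base-4 digits, most-significant digit = first base, in one ``uint64`` limb
for k <= 31 or two limbs (high limb = first k-32 bases) for 31 < k <= 63.

Canonicalisation follows the Jellyfish convention: the lexicographic minimum of
a k-mer and its reverse complement. For odd k the two can never be equal, so
the canonical form is unambiguous. Reverse-complement codes of all windows are
obtained for free by running the forward coder over the reversed complemented
sequence, which keeps everything vectorised.
"""

from __future__ import annotations

import numpy as np

SENTINEL = np.uint8(255)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE_LUT[_b] = _i

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rc_byte(x: int) -> int:
    # reverse the four 2-bit fields of a byte, then complement (base ^ 3)
    y = ((x & 0x03) << 6) | ((x & 0x0C) << 2) | ((x & 0x30) >> 2) | ((x & 0xC0) >> 6)
    return (~y) & 0xFF


_RC_BYTE_LUT = np.array([_rc_byte(i) for i in range(256)], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode uint8 base codes (no sentinels) back to a string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    """Complement base codes, preserving sentinels."""
    out = codes ^ np.uint8(3)
    out[codes == SENTINEL] = SENTINEL
    return out


def _limb_codes(bb: np.ndarray, k: int, m: int) -> np.ndarray:
    """Base-4 codes of all m windows of length k over sanitised digits bb."""
    codes = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes <<= two
        codes |= bb[j : j + m]
    return codes


def _window_valid(b: np.ndarray, k: int) -> np.ndarray:
    inv = (b == SENTINEL).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(inv)))
    return (cs[k:] - cs[:-k]) == 0


def forward_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward window codes over encoded array ``b``.

    Returns ``(codes, valid)`` where codes has shape (m,) for k <= 31 or
    (m, 2) limbs [hi, lo] for k <= 63, m = len(b) - k + 1.
    """
    n = b.size
    m = n - k + 1
    if m <= 0:
        shape = (0,) if k <= 31 else (0, 2)
        return np.zeros(shape, dtype=np.uint64), np.zeros(0, dtype=bool)
    bb = np.where(b == SENTINEL, 0, b).astype(np.uint64)
    valid = _window_valid(b, k)
    if k <= 31:
        return _limb_codes(bb, k, m), valid
    # two limbs: hi = first k-32 bases, lo = last 32 bases
    k_hi = k - 32
    hi = _limb_codes(bb, k_hi, n - k_hi + 1)[:m]
    lo = _limb_codes(bb, 32, n - 31)[k_hi : k_hi + m]
    return np.stack([hi, lo], axis=1), valid


def canonical_window_codes(b: np.ndarray, k: int) -> np.ndarray:
    """Canonical codes of every valid k-window of ``b`` (order preserved)."""
    fwd, valid = forward_codes(b, k)
    if fwd.shape[0] == 0:
        return fwd
    brc = complement(b)[::-1]
    rev, _ = forward_codes(brc, k)
    rev = rev[::-1]  # align: rc of window i is forward window n-k-i of brc
    if k <= 31:
        canon = np.minimum(fwd, rev)
        return canon[valid]
    swap = (rev[:, 0] < fwd[:, 0]) | ((rev[:, 0] == fwd[:, 0]) & (rev[:, 1] < fwd[:, 1]))
    canon = np.where(swap[:, None], rev, fwd)
    return canon[valid]


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed codes; single-limb k <= 31 only."""
    if k > 31:
        raise ValueError("revcomp_codes supports k <= 31 (single-limb codes)")
    v = np.ascontiguousarray(codes, dtype="<u8").view(np.uint8).reshape(-1, 8)
    rc = np.ascontiguousarray(_RC_BYTE_LUT[v][:, ::-1]).view("<u8").ravel()
    return rc >> np.uint64(64 - 2 * k)


def canonicalize_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """min(code, revcomp) elementwise; single-limb k <= 31 only."""
    return np.minimum(codes, revcomp_codes(codes, k))


def kmer_to_code(kmer: str, k: int):
    """Pack one k-mer string; returns int (k <= 31) or (hi, lo) tuple."""
    if len(kmer) != k:
        raise ValueError(f"expected length-{k} k-mer, got {len(kmer)}")
    b = encode(kmer)
    if (b == SENTINEL).any():
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    val = 0
    for d in b:
        val = (val << 2) | int(d)
    if k <= 31:
        return val
    return (val >> 64, val & 0xFFFFFFFFFFFFFFFF)


def code_to_kmer(code, k: int) -> str:
    """Unpack a code (int or (hi, lo)) back to its k-mer string."""
    if k <= 31:
        val = int(code)
    else:
        hi, lo = (int(code[0]), int(code[1]))
        val = (hi << 64) | lo
    chars = []
    for shift in range(2 * (k - 1), -1, -2):
        chars.append("ACGT"[(val >> shift) & 3])
    return "".join(chars)


def codes_to_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Vector decode of packed codes to strings."""
    n = codes.shape[0]
    if n == 0:
        return []
    out = np.empty((n, k), dtype=np.uint8)
    if k <= 31:
        c = codes.astype(np.uint64)
        for j, shift in enumerate(range(2 * (k - 1), -1, -2)):
            out[:, j] = ((c >> np.uint64(shift)) & np.uint64(3)).astype(np.uint8)
    else:
        hi, lo = codes[:, 0], codes[:, 1]
        k_hi = k - 32
        for j, shift in enumerate(range(2 * (k_hi - 1), -1, -2)):
            out[:, j] = ((hi >> np.uint64(shift)) & np.uint64(3)).astype(np.uint8)
        for j, shift in enumerate(range(62, -1, -2)):
            out[:, k_hi + j] = ((lo >> np.uint64(shift)) & np.uint64(3)).astype(np.uint8)
    flat = _DECODE_LUT[out].tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(n)]


def revcomp_str(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGT only)."""
    return decode(complement(encode(seq))[::-1])
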