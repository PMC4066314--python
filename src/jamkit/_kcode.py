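"""2-bit k-mer integer coding shared across modules.

Bases are coded A=0, C=1, G=2, T=3 most-significant-first, so a k-mer's
integer code is read left to right.  The canonical form of a k-mer is the
numerically smaller of its code and its reverse-complement code; odd k
guarantees the two never tie.  Anything that is not ACGT (masked bases,
separators) is coded 255 and poisons every window containing it.
"""

from __future__ import annotations

import numpy as np

INVALID = np.uint8(255)

_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i  # soft-masked bases still count

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Sequence -> uint8 base codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def decode_kmer(code: int, k: int) -> str:
    out = np.empty(k, dtype=np.uint8)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = c & 3
        c >>= 2
    return decode_bases(out)


def encode_kmer(kmer: str) -> int:
    codes = encode(kmer)
    if (codes == INVALID).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    c = 0
    for b in codes:
        c = (c << 2) | int(b)
    return c


def kmer_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes over a base-code array.

    Returns (codes, valid) of length len(base_codes) - k + 1; windows
    containing an invalid base are flagged False in `valid` (their code is
    meaningless).
    """
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | base_codes[j : j + n].astype(np.uint64)
    bad = (base_codes == INVALID).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    # invalid windows got garbage from code 255; zero them for tidiness
    codes[~valid] = 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit k-mer codes."""
    c = codes.astype(np.uint64, copy=True)
    rc = np.zeros_like(c)
    three = np.uint64(3)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (three - (c & three))
        c >>= np.uint64(2)
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes and a boolean array: True where the forward code won."""
    rc = revcomp_codes(codes, k)
    fwd = codes <= rc
    return np.where(fwd, codes, rc), fwd


def canonical_kmer(kmer: str) -> str:
    k = len(kmer)
    code = np.array([encode_kmer(kmer)], dtype=np.uint64)
    canon, _ = canonical_codes(code, k)
    return decode_kmer(int(canon[0]), k)


def revcomp_str(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def base_at(code: int, pos: int, k: int) -> int:
    """Base code at 1-based position `pos` of a k-mer integer code."""
    shift = 2 * (k - pos)
    return (int(code) >> shift) & 3
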