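"""Low-level nucleotide encoding shared by the counting modules.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, separators) is 4.
The complement of a valid code c is 3 - c.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_RC_TABLE)[::-1]


def concat_with_separators(seqs: list[str]) -> np.ndarray:
    """Encode sequences into one code array, joined by invalid-code separators
    so that no k-mer window can span two sequences."""
    return encode("N".join(seqs))


def window_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all length-k windows plus a validity mask.

    Returns (kmer_codes, valid) where kmer_codes[i] packs codes[i:i+k] into a
    uint64 (2 bits per base, first base most significant) and valid[i] is True
    iff the window contains no code >= 4.  Rolling construction keeps memory at
    O(n) rather than materialising an (n, k) window matrix.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.uint64)
    m = n - k + 1
    kmers = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        kmers |= c[i : m + i] << np.uint64(2 * (k - 1 - i))
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return kmers, valid


def window_rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complement of each window (same order)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    # complement garbage codes too; masked out by the validity mask upstream
    comp = (np.uint64(3) - np.minimum(codes, 3).astype(np.uint64))
    m = n - k + 1
    rc = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        rc |= comp[i : m + i] << np.uint64(2 * i)
    return rc


def kmer_code_to_str(code: int, k: int) -> str:
    out = []
    for i in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * i)) & 3])
    return "".join(out)
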