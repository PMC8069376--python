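"""Low-level sequence byte/array utilities shared across modules.

Sequences are handled as ASCII ``bytes``/uint8 numpy arrays internally.
Only the alphabet {A, C, G, T, N} is legal; N is permitted in reference
sequences but is excluded from k-mer space and from probes.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

# 2-bit codes; 255 marks anything outside {A,C,G,T} (including N).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y


def validate_dna(seq: str, *, allow_n: bool = True) -> None:
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"illegal DNA character(s): {sorted(bad)!r}")


def to_bytes(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype=np.uint8)


def to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; raises on any other character."""
    validate_dna(seq)
    return to_str(revcomp_array(to_bytes(seq)))


def gc_fraction(seq: str | np.ndarray) -> float:
    arr = to_bytes(seq) if isinstance(seq, str) else seq
    n = arr.size
    if n == 0:
        return 0.0
    gc = np.count_nonzero((arr == ord("G")) | (arr == ord("C")))
    return gc / n


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``arr`` (uint8 ASCII); windows touching
    any non-ACGT byte get code -1. Returns int64 array of length len-k+1."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes2 = _CODE[arr].astype(np.int64)
    bad = codes2 == 255
    codes2[bad] = 0
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out += codes2[j : n - k + 1 + j] << (2 * (k - 1 - j))
    if bad.any():
        # invalidate any window overlapping a bad base
        badwin = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64))[k - 1 : n]
        out[badwin > 0] = -1
    return out
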