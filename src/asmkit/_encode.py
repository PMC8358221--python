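"""2-bit nucleotide encoding shared by the k-mer counter and the overlap assembler.

A k-mer (k <= 31) is packed into a uint64, two bits per base, A=0 C=1 G=2 T=3.
Windows containing any non-ACGT symbol are masked out.
"""
from __future__ import annotations

import numpy as np

INVALID = np.uint8(255)

_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

MAX_K = 31  # 2k bits must fit a uint64


def encode(seq: str | bytes) -> np.ndarray:
    """Map a sequence to uint8 base codes (255 for ambiguous symbols)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def window_codes(codes: np.ndarray, k: int, canonical: bool = True):
    """Packed integer codes for every k-window of a base-code array.

    Returns ``(win, valid)`` where ``win`` is a uint64 array of length
    ``len(codes) - k + 1`` and ``valid`` marks windows free of ambiguous bases.
    With ``canonical=True`` each window code is the minimum of the forward code
    and the code of its reverse complement (strand-independent counting).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    ok = codes != INVALID
    c = np.where(ok, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + n]
    # valid window <=> all k bases valid
    cs = np.concatenate(([0], np.cumsum(ok, dtype=np.int64)))
    valid = (cs[k:] - cs[:-k]) == k
    if not canonical:
        return fwd, valid
    comp = np.uint64(3) - c
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | comp[j : j + n]
    return np.minimum(fwd, rev), valid


def decode(code: int, k: int) -> str:
    """Inverse of the 2-bit packing, for display/round-trip use."""
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))
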