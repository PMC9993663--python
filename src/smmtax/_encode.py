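"""2-bit nucleotide encoding shared by the scorer and the segmenter.

A=0, C=1, G=2, T=3; every other (IUPAC-ambiguous) symbol maps to 4 and
invalidates any k-mer window that covers it.
"""

from __future__ import annotations

import numpy as np

AMBIG = 4

_LUT = np.full(256, AMBIG, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _LUT[ord(base)] = i
    _LUT[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (0-3, ambiguous=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded sequence; ambiguity is preserved."""
    out = codes[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


def window_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling integer codes of every length-``w`` window.

    Returns ``(wcodes, valid)`` of length ``len(codes) - w + 1``:
    ``wcodes[i]`` is the base-4 packing of ``codes[i:i+w]`` (meaningful
    only where ``valid[i]``), ``valid[i]`` is True iff the window holds
    no ambiguous base.
    """
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    clipped = np.where(codes < 4, codes, 0).astype(np.int64)
    wcodes = np.zeros(n, dtype=np.int64)
    for j in range(w):
        wcodes = wcodes * 4 + clipped[j : j + n]
    bad = (codes >= 4).astype(np.int64)
    cums = np.concatenate(([0], np.cumsum(bad)))
    valid = (cums[w:] - cums[:-w]) == 0
    return wcodes, valid
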