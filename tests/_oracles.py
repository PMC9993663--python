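"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's packed-array code paths: counts
are plain dictionaries of k-mer strings, probabilities exact Fractions,
and the incremental-slider check uses vectorized whole-table arithmetic
with no per-step updates.
"""

import math
from fractions import Fraction

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_score(genome_records, k, delta, read):
    """Total log-likelihood of a read, max over strands, exact counts."""
    kmer_counts: dict[str, int] = {}
    trans_counts: dict[str, int] = {}
    for rec in genome_records:
        seq = rec.residues
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                kmer_counts[w] = kmer_counts.get(w, 0) + 1
        for i in range(len(seq) - k):
            w = seq[i : i + k + 1]
            if set(w) <= set("ACGT"):
                trans_counts[w] = trans_counts.get(w, 0) + 1
    total_kmers = sum(kmer_counts.values())
    d = Fraction(delta)

    def initial_p(w):
        return (kmer_counts.get(w, 0) + d) / (total_kmers + d * 4**k)

    def trans_p(w, x):
        row = sum(trans_counts.get(w + b, 0) for b in "ACGT")
        return (trans_counts.get(w + x, 0) + d) / (row + 4 * d)

    def strand_score(seq):
        first = None
        for i in range(len(seq) - k + 1):
            if set(seq[i : i + k]) <= set("ACGT"):
                first = seq[i : i + k]
                break
        if first is None:
            return None
        terms = [math.log(initial_p(first))]
        for i in range(len(seq) - k):
            win = seq[i : i + k + 1]
            if set(win) <= set("ACGT"):
                terms.append(math.log(trans_p(win[:k], win[k])))
        return math.fsum(terms) if len(terms) >= 2 else None

    scores = [s for s in (strand_score(read), strand_score(revcomp(read))) if s is not None]
    return max(scores) if scores else None


def _entropies(counts):
    """H for a batch of profiles, shape (S, n_ctx, 4) -> (S,)."""
    row = counts.sum(axis=2)
    n = counts.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(counts > 0, counts * np.log2(np.maximum(counts, 1)), 0.0).sum(axis=(1, 2))
        s1 = np.where(row > 0, row * np.log2(np.maximum(row, 1)), 0.0).sum(axis=1)
    out = np.zeros_like(s1)
    nz = n > 0
    out[nz] = (s1[nz] - s2[nz]) / n[nz]
    return out, n


def fresh_divergences(codes, m, lo, hi, min_len):
    """MJSD at every admissible split by whole-table recomputation.

    Left/right profiles at each split are taken from a cumulative count
    table (windows keyed to their start position, context overhanging
    the split); entropies are evaluated in full per split.
    """
    from smmtax._encode import window_codes

    wcodes, valid = window_codes(codes, m + 1)
    i_hi = min(hi, len(codes) - m)
    n_flat = 4 ** (m + 1)
    span = i_hi - lo
    table = np.zeros((span + 1, n_flat), dtype=np.float64)
    sel = valid[lo:i_hi]
    table[np.arange(1, span + 1)[sel], wcodes[lo:i_hi][sel]] = 1.0
    cum = np.cumsum(table, axis=0)
    s0, s_end = lo + min_len, hi - min_len
    if s_end <= s0:
        return np.empty(0), s0
    splits = np.arange(s0, s_end)
    idx = np.clip(splits - lo, 0, span)
    left = cum[idx].reshape(-1, 4**m, 4)
    whole = cum[-1].reshape(1, 4**m, 4)
    right = whole - left
    h_l, n_l = _entropies(left)
    h_r, n_r = _entropies(right)
    h_u, n_u = _entropies(np.broadcast_to(whole, left.shape))
    n = n_l + n_r
    d = h_u - (n_l * h_l + n_r * h_r) / n
    return np.maximum(d, 0.0), s0
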