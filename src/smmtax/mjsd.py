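"""Markovian Jensen-Shannon divergence segmentation and clustering.

A genome is recursively split at the position maximising the MJSD
between the two resulting halves, computed from order-m context counts:

    H^m(p) = -sum_w P(w) sum_x P(x|w) log2 P(x|w)
    D(L, R) = H(L+R) - (n_L/n) H(L) - (n_R/n) H(R)

where the weights are (m+1)-mer count-total proportions. The split
statistic is evaluated at *every* admissible position by sliding the
split point one nucleotide at a time and adjusting the entropy
accumulators for the single context window that changes sides —
no fresh recomputation — which makes a full pass linear in the
interval length for fixed m.

Significance of a split uses, by default, an analytic chi-square
approximation with a maximum-statistic correction for the number of
candidate positions; a Monte-Carlo permutation mode is available as
the calibration reference. Segments are then agglomeratively merged
into compositional clusters, and clusters smaller than a fixed
fraction of the genome are discarded — the retained clusters are the
sampling pool for calibration fragments.

Each (m+1)-mer window belongs to the segment containing its start
position (the context may overhang the segment end), so segment
profiles add exactly: the sum of all segment profiles equals the
whole-genome profile, and D >= 0 holds exactly by concavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._encode import encode, window_codes
from .seqio import SequenceRecord

LN2 = math.log(2.0)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class CountProfile:
    """Exact order-m context counts: shape (4^m, 4), context x next base."""

    m: int
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, other: "CountProfile") -> "CountProfile":
        self._check(other)
        return CountProfile(self.m, self.counts + other.counts)

    def subtract(self, other: "CountProfile") -> "CountProfile":
        self._check(other)
        out = self.counts - other.counts
        if (out < 0).any():
            raise ValueError("profile subtraction produced negative counts")
        return CountProfile(self.m, out)

    def _check(self, other: "CountProfile") -> None:
        if self.m != other.m:
            raise ValueError(f"profile order mismatch: {self.m} != {other.m}")


@dataclass
class Segment:
    """Half-open genome interval [start, end) with its count profile."""

    start: int
    end: int
    profile: CountProfile

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Cluster:
    """Compositionally homogeneous group of (non-contiguous) segments."""

    members: list[Segment]
    profile: CountProfile

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.members)

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(sorted(s.start for s in self.members))


@dataclass(frozen=True)
class DivergenceResult:
    D: float  # bits/symbol
    split: int  # absolute position; -1 for a no-split result
    p_value: float


@dataclass(frozen=True)
class SegmentationConfig:
    m: int = 2
    alpha_segment: float = 0.05
    p_cluster: float = 1e-5
    min_segment_len: int = 5000
    min_cluster_frac: float = 1e-5  # "less than 0.001% of the genome" discarded

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_segment < 1:
            raise ValueError("alpha_segment must be in [0, 1)")
        if not 0 < self.p_cluster < 1:
            raise ValueError("p_cluster must be in (0, 1)")
        if self.m < 0:
            raise ValueError("m must be >= 0")


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    return encode(seq)


def count_contexts(seq, m: int, start: int = 0, end: int | None = None) -> CountProfile:
    """Count (m+1)-mer windows starting in [start, end).

    Windows may overhang ``end`` (context truncated only at the sequence
    end); windows containing an ambiguous base are skipped. This start-
    position convention makes profiles of a partition sum exactly to the
    whole-sequence profile.
    """
    codes = _as_codes(seq)
    n = codes.size
    if end is None:
        end = n
    if end - start < m + 1:
        raise ValueError(f"interval [{start}, {end}) shorter than m+1 = {m + 1}")
    wcodes, valid = window_codes(codes, m + 1)
    i_hi = min(end, n - m)
    sel = wcodes[start:i_hi][valid[start:i_hi]]
    flat = np.bincount(sel, minlength=4 ** (m + 1))
    return CountProfile(m, flat.reshape(4**m, 4).astype(np.int64))


def markov_entropy(profile: CountProfile) -> float:
    """H in bits/symbol from maximum-likelihood P(w), P(x|w); 0 <= H <= 2."""
    n = profile.total
    if n == 0:
        raise ValueError("entropy of an empty profile is undefined")
    c = profile.counts.astype(np.float64)
    row = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(c > 0, c * np.log2(np.where(c > 0, c, 1.0)), 0.0).sum()
        s1 = np.where(row > 0, row * np.log2(np.where(row > 0, row, 1.0)), 0.0).sum()
    return float((s1 - s2) / n)


def mjsd(left: CountProfile, right: CountProfile) -> float:
    """MJSD in bits between two profiles; >= 0, 0 iff distributions match."""
    if left.m != right.m:
        raise ValueError(f"profile order mismatch: {left.m} != {right.m}")
    n_l, n_r = left.total, right.total
    if n_l == 0 or n_r == 0:
        raise ValueError("MJSD requires both profiles non-empty")
    if np.array_equal(left.counts, right.counts):
        return 0.0  # identity exact, independent of rounding
    n = n_l + n_r
    h = markov_entropy(left.add(right))
    d = h - (n_l / n) * markov_entropy(left) - (n_r / n) * markov_entropy(right)
    return max(d, 0.0)  # clamp -0.0 / tiny negative rounding


@njit(cache=False)
def _slide_divergences(
    wcodes: np.ndarray,
    valid: np.ndarray,
    n_ctx: int,
    i_lo: int,
    i_hi: int,
    s0: int,
    s_end: int,
) -> np.ndarray:  # pragma: no cover - numba-compiled
    """MJSD at every candidate split s in [s0, s_end).

    ``wcodes``/``valid`` are whole-sequence window arrays indexed by
    absolute window start; windows live at starts [i_lo, i_hi). At split
    s the left profile holds windows [i_lo, s), the right [s, i_hi).
    Entropy accumulators (S1 = sum r_w log2 r_w, S2 = sum c_wx log2 c_wx,
    H = (S1 - S2)/n) are adjusted per step for the one window changing
    sides.
    """
    cnt_l = np.zeros((n_ctx, 4), dtype=np.int64)
    row_l = np.zeros(n_ctx, dtype=np.int64)
    cnt_r = np.zeros((n_ctx, 4), dtype=np.int64)
    row_r = np.zeros(n_ctx, dtype=np.int64)
    for i in range(i_lo, min(s0, i_hi)):
        if valid[i]:
            w = wcodes[i] >> 2
            x = wcodes[i] & 3
            cnt_l[w, x] += 1
            row_l[w] += 1
    for i in range(max(s0, i_lo), i_hi):
        if valid[i]:
            w = wcodes[i] >> 2
            x = wcodes[i] & 3
            cnt_r[w, x] += 1
            row_r[w] += 1

    s1_l = 0.0
    s2_l = 0.0
    s1_r = 0.0
    s2_r = 0.0
    n_l = 0
    n_r = 0
    s1_u = 0.0
    s2_u = 0.0
    for w in range(n_ctx):
        rl = row_l[w]
        rr = row_r[w]
        n_l += rl
        n_r += rr
        if rl > 0:
            s1_l += rl * math.log2(rl)
        if rr > 0:
            s1_r += rr * math.log2(rr)
        ru = rl + rr
        if ru > 0:
            s1_u += ru * math.log2(ru)
        for x in range(4):
            cl = cnt_l[w, x]
            cr = cnt_r[w, x]
            if cl > 0:
                s2_l += cl * math.log2(cl)
            if cr > 0:
                s2_r += cr * math.log2(cr)
            cu = cl + cr
            if cu > 0:
                s2_u += cu * math.log2(cu)

    n = n_l + n_r
    h_u = (s1_u - s2_u) / n if n > 0 else 0.0

    out = np.empty(s_end - s0, dtype=np.float64)
    for s in range(s0, s_end):
        d = h_u - ((s1_l - s2_l) + (s1_r - s2_r)) / n if n > 0 else 0.0
        out[s - s0] = d if d > 0.0 else 0.0
        # transfer window starting at s from right to left for split s+1
        if i_lo <= s < i_hi and valid[s]:
            w = wcodes[s] >> 2
            x = wcodes[s] & 3
            cl = cnt_l[w, x]
            s2_l += (cl + 1) * math.log2(cl + 1) - (cl * math.log2(cl) if cl > 0 else 0.0)
            cnt_l[w, x] = cl + 1
            rl = row_l[w]
            s1_l += (rl + 1) * math.log2(rl + 1) - (rl * math.log2(rl) if rl > 0 else 0.0)
            row_l[w] = rl + 1
            cr = cnt_r[w, x]
            s2_r += ((cr - 1) * math.log2(cr - 1) if cr > 1 else 0.0) - cr * math.log2(cr)
            cnt_r[w, x] = cr - 1
            rr = row_r[w]
            s1_r += ((rr - 1) * math.log2(rr - 1) if rr > 1 else 0.0) - rr * math.log2(rr)
            row_r[w] = rr - 1
    return out


def divergence_profile(
    seq, m: int, lo: int, hi: int, min_segment_len: int
) -> tuple[np.ndarray, int]:
    """MJSD at every admissible split of [lo, hi); returns (D values, s0).

    Candidate splits are [lo + min_segment_len, hi - min_segment_len).
    """
    codes = _as_codes(seq)
    wcodes, valid = window_codes(codes, m + 1)
    i_hi = min(hi, codes.size - m)
    s0 = lo + min_segment_len
    s_end = hi - min_segment_len
    if s_end <= s0:
        return np.empty(0, dtype=np.float64), s0
    d = _slide_divergences(wcodes, valid.astype(np.bool_), 4**m, lo, i_hi, s0, s_end)
    return d, s0


def _effective_candidates(n: int, m: int, n_candidates: int) -> float:
    """Effective number of independent split candidates.

    Neighbouring split statistics are almost perfectly correlated, so
    the raw candidate count wildly overcorrects. The permutation null
    (``split_significance_mc``, the calibration reference) shows the
    effective count growing like c * (m+1) * log2(n) with c close to
    1.5 over n = 2-20 kb and m = 0-2; that rule is used here, capped
    by the actual candidate count.
    """
    if n_candidates <= 1:
        return float(n_candidates)
    rule = 1.5 * (m + 1) * math.log2(n)
    return max(1.0, min(float(n_candidates), rule))


def split_significance(
    D: float,
    n: int,
    m: int,
    n_candidates: int = 1,
) -> float:
    """Analytic p-value of an observed MJSD maximum.

    The statistic 2 n ln(2) D is referred to a chi-square with 3*4^m
    degrees of freedom; the maximum over candidate positions is
    corrected as p = 1 - F(x)^n_eff with the effective candidate
    count of :func:`_effective_candidates`. The Monte-Carlo mode is
    the authoritative reference where the approximation matters.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if D <= 0:
        return 1.0
    x = 2.0 * n * LN2 * D
    df = 3 * 4**m
    log_cdf = stats.chi2.logcdf(x, df)
    return float(-math.expm1(_effective_candidates(n, m, n_candidates) * log_cdf))


def split_significance_mc(
    seq,
    m: int,
    lo: int,
    hi: int,
    min_segment_len: int,
    D_obs: float,
    n_replicates: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value: shuffle the interval, recompute the max D."""
    rng = np.random.default_rng(rng)
    codes = _as_codes(seq).copy()
    exceed = 0
    for _ in range(n_replicates):
        perm = codes[lo:hi].copy()
        rng.shuffle(perm)
        shuffled = codes.copy()
        shuffled[lo:hi] = perm
        d, _ = divergence_profile(shuffled, m, lo, hi, min_segment_len)
        if d.size and d.max() >= D_obs:
            exceed += 1
    return (1 + exceed) / (n_replicates + 1)


def best_split(
    seq, m: int, lo: int, hi: int, min_segment_len: int
) -> DivergenceResult:
    """Argmax-MJSD split of [lo, hi) with its analytic p-value.

    Intervals shorter than twice ``min_segment_len`` yield the no-split
    result (D = 0, p = 1). Ties break to the smallest position.
    """
    d, s0 = divergence_profile(seq, m, lo, hi, min_segment_len)
    if d.size == 0:
        return DivergenceResult(0.0, -1, 1.0)
    idx = int(np.argmax(d))
    codes = _as_codes(seq)
    n = count_contexts(codes, m, lo, hi).total
    p = split_significance(float(d[idx]), n, m, n_candidates=d.size)
    return DivergenceResult(float(d[idx]), s0 + idx, p)


def segment_genome(seq, config: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Recursive binary MJSD segmentation; segments tile [0, L) exactly."""
    codes = _as_codes(seq)
    length = codes.size
    boundaries: list[int] = []
    stack = [(0, length)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * config.min_segment_len:
            continue
        res = best_split(codes, config.m, lo, hi, config.min_segment_len)
        if res.split >= 0 and res.p_value < config.alpha_segment:
            boundaries.append(res.split)
            stack.append((lo, res.split))
            stack.append((res.split, hi))
    edges = [0] + sorted(boundaries) + [length]
    return [
        Segment(a, b, count_contexts(codes, config.m, a, b))
        for a, b in zip(edges[:-1], edges[1:])
    ]


def _pair_p(a: Cluster, b: Cluster, m: int) -> float:
    d = mjsd(a.profile, b.profile)
    n = a.profile.total + b.profile.total
    return split_significance(d, n, m, n_candidates=1)


def cluster_segments(
    segments: Sequence[Segment], config: SegmentationConfig = SegmentationConfig()
) -> list[Cluster]:
    """Agglomerative merging of segments into compositional clusters.

    Repeatedly merge the pair with the *largest* MJSD p-value (least
    significant divergence, computed on summed profiles) while that
    p-value exceeds ``p_cluster``; ties break to the smallest member
    start coordinates. Deterministic.
    """
    if not segments:
        raise ValueError("need at least one segment")
    clusters = [Cluster([s], CountProfile(s.profile.m, s.profile.counts.copy())) for s in segments]
    m = segments[0].profile.m
    while len(clusters) > 1:
        best: tuple[float, tuple, tuple, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                p = _pair_p(clusters[i], clusters[j], m)
                cand = (-p, clusters[i].key, clusters[j].key)
                if best is None or cand < best[:3]:
                    best = (*cand, i, j)
        p_best = -best[0]
        if p_best <= config.p_cluster:
            break
        i, j = best[3], best[4]
        merged = Cluster(
            members=sorted(clusters[i].members + clusters[j].members, key=lambda s: s.start),
            profile=clusters[i].profile.add(clusters[j].profile),
        )
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    clusters.sort(key=lambda c: c.key)
    return clusters


def filter_clusters(
    clusters: Sequence[Cluster],
    genome_length: int,
    config: SegmentationConfig = SegmentationConfig(),
    predicate: Callable[[Cluster], bool] | None = None,
) -> list[Cluster]:
    """Drop clusters strictly smaller than min_cluster_frac x genome length.

    ``predicate`` is a pluggable extra screen (e.g. a contaminant
    filter) applied to the survivors; the default keeps everything.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    # compare as a fraction of the genome so the "less than" stays strict
    kept = [
        c for c in clusters if not c.total_length / genome_length < config.min_cluster_frac
    ]
    if predicate is not None:
        kept = [c for c in kept if predicate(c)]
    return kept


class MJSDSegmenter:
    """Estimator-style wrapper: fit a sequence, expose segments/clusters.

    Parameters mirror :class:`SegmentationConfig`. After ``fit``:

    - ``segments_``: list of Segment tiling the sequence
    - ``clusters_``: all clusters
    - ``retained_clusters_``: clusters surviving the size filter
    - ``labels_``: cluster index per segment (coordinate order)
    """

    def __init__(
        self,
        m: int = 2,
        alpha_segment: float = 0.05,
        p_cluster: float = 1e-5,
        min_segment_len: int = 5000,
        min_cluster_frac: float = 1e-5,
        cluster_predicate: Callable[[Cluster], bool] | None = None,
    ):
        self.m = m
        self.alpha_segment = alpha_segment
        self.p_cluster = p_cluster
        self.min_segment_len = min_segment_len
        self.min_cluster_frac = min_cluster_frac
        self.cluster_predicate = cluster_predicate

    def get_params(self, deep: bool = True) -> dict:
        return {
            "m": self.m,
            "alpha_segment": self.alpha_segment,
            "p_cluster": self.p_cluster,
            "min_segment_len": self.min_segment_len,
            "min_cluster_frac": self.min_cluster_frac,
            "cluster_predicate": self.cluster_predicate,
        }

    def set_params(self, **params) -> "MJSDSegmenter":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            m=self.m,
            alpha_segment=self.alpha_segment,
            p_cluster=self.p_cluster,
            min_segment_len=self.min_segment_len,
            min_cluster_frac=self.min_cluster_frac,
        )

    def fit(self, X) -> "MJSDSegmenter":
        """Segment and cluster one sequence (str, SequenceRecord or codes)."""
        config = self._config()
        codes = _as_codes(X)
        self.segments_ = segment_genome(codes, config)
        self.clusters_ = cluster_segments(self.segments_, config)
        self.retained_clusters_ = filter_clusters(
            self.clusters_, codes.size, config, predicate=self.cluster_predicate
        )
        seg_to_cluster = {
            id(seg): idx for idx, c in enumerate(self.clusters_) for seg in c.members
        }
        self.labels_ = np.array([seg_to_cluster[id(s)] for s in self.segments_])
        return self

    def fit_predict(self, X) -> np.ndarray:
        return self.fit(X).labels_
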