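"""Fixed-order standard Markov models (SMM) of genomes and read scoring.

A genome model of order ``k`` holds the pseudocount-smoothed initial
k-mer distribution P(w) and the transition distribution P(x | w) over
all 4^k contexts. A read's raw score is its total natural-log
likelihood under the model,

    log P(w_1..k) + sum_{i>k} log P(x_i | x_{i-k}..x_{i-1}),

evaluated on both strands with the maximum returned (shotgun reads have
unknown strand). Models are built on the fly and never persisted; the
scoring driver reuses one count/probability buffer per worker, resetting
it as each genome is modeled, so memory stays flat in the number of
genomes.

Any (k+1)-mer window containing an ambiguous base contributes nothing to
counts and is skipped in scoring; a read with no unambiguous (k+1)-mer
is unscorable.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._encode import encode, revcomp_codes, window_codes
from .seqio import SequenceRecord, read_fasta

logger = logging.getLogger(__name__)

#: Orders the method has been validated at.
VALIDATED_ORDERS = (10, 11, 12)
#: Hard order cap (dense 4^(k+1) tables; memory guard).
MAX_ORDER = 14


@dataclass
class MarkovModel:
    """Order-``k`` Markov model of one genome (natural-log tables)."""

    genome_id: str
    k: int
    delta: float
    initial_logprob: np.ndarray  # shape (4^k,)
    transition_logprob: np.ndarray  # shape (4^k, 4)

    def initial_prob_sum(self) -> float:
        return float(np.exp(self.initial_logprob).sum())

    def transition_prob_sums(self) -> np.ndarray:
        return np.exp(self.transition_logprob).sum(axis=1)


@dataclass(frozen=True)
class ReadScore:
    read_id: str
    genome_id: str
    raw_score: float
    read_length: int


@dataclass
class ScoreTable:
    """Per read, ReadScores sorted by raw_score desc, ties by genome_id asc."""

    scores: dict[str, list[ReadScore]] = field(default_factory=dict)
    unscorable: list[str] = field(default_factory=list)

    def __getitem__(self, read_id: str) -> list[ReadScore]:
        return self.scores[read_id]

    def __len__(self) -> int:
        return len(self.scores)

    def best(self, read_id: str) -> ReadScore:
        return self.scores[read_id][0]


def _check_order(k: int) -> None:
    if not 1 <= k <= MAX_ORDER:
        raise ValueError(f"model order must be in 1..{MAX_ORDER}, got {k}")
    if k not in VALIDATED_ORDERS:
        warnings.warn(
            f"order {k} is outside the validated range {VALIDATED_ORDERS}",
            stacklevel=3,
        )


class _ModelBuffer:
    """Reusable count/probability tables of fixed order.

    Kept "global" across genomes within a worker and reset as each
    genome is modeled, so the large 4^k tables are allocated once.
    """

    def __init__(self, k: int, delta: float):
        if delta <= 0:
            raise ValueError(f"pseudocount must be positive, got {delta}")
        self.k = k
        self.delta = delta
        n_ctx = 4**k
        self.kmer_counts = np.zeros(n_ctx, dtype=np.int64)
        self.trans_counts = np.zeros((n_ctx, 4), dtype=np.int64)
        self.initial_logprob = np.empty(n_ctx, dtype=np.float64)
        self.transition_logprob = np.empty((n_ctx, 4), dtype=np.float64)

    def reset(self) -> None:
        self.kmer_counts[:] = 0
        self.trans_counts[:] = 0

    def count(self, records: Sequence[SequenceRecord]) -> None:
        """Accumulate k-mer and (k+1)-mer counts; no context spans a record."""
        k = self.k
        for rec in records:
            codes = encode(rec.residues)
            kcodes, kvalid = window_codes(codes, k)
            if kcodes.size:
                self.kmer_counts += np.bincount(kcodes[kvalid], minlength=4**k)
            tcodes, tvalid = window_codes(codes, k + 1)
            if tcodes.size:
                flat = np.bincount(tcodes[tvalid], minlength=4 ** (k + 1))
                self.trans_counts += flat.reshape(4**self.k, 4)

    def finalize(self, genome_id: str) -> MarkovModel:
        d = self.delta
        kc = self.kmer_counts
        np.log((kc + d) / (kc.sum() + d * kc.size), out=self.initial_logprob)
        tc = self.trans_counts
        row = tc.sum(axis=1, keepdims=True)
        np.log((tc + d) / (row + 4 * d), out=self.transition_logprob)
        return MarkovModel(
            genome_id=genome_id,
            k=self.k,
            delta=d,
            initial_logprob=self.initial_logprob,
            transition_logprob=self.transition_logprob,
        )


def build_model(
    genome: Sequence[SequenceRecord], k: int, delta: float = 1.0, genome_id: str | None = None
) -> MarkovModel:
    """Build the order-``k`` model of one genome (all records jointly).

    Every transition cell starts at the pseudocount ``delta``; a genome
    shorter than k+1 therefore yields the uniform pure-pseudocount model.
    The returned model owns its tables (no buffer aliasing).
    """
    _check_order(k)
    if not genome:
        raise ValueError("genome must contain at least one record")
    buf = _ModelBuffer(k, delta)
    buf.count(genome)
    model = buf.finalize(genome_id or genome[0].id)
    model.initial_logprob = model.initial_logprob.copy()
    model.transition_logprob = model.transition_logprob.copy()
    return model


@dataclass(frozen=True)
class _EncodedRead:
    """Strand-wise context/next-base index arrays for fast table lookups."""

    read_id: str
    length: int
    first_kmer: tuple[int, int]  # first valid k-mer code per strand (-1 if none)
    contexts: tuple[np.ndarray, np.ndarray]
    next_bases: tuple[np.ndarray, np.ndarray]

    @property
    def scorable(self) -> bool:
        return self.next_bases[0].size > 0


def _encode_read(read: SequenceRecord, k: int) -> _EncodedRead:
    fwd = encode(read.residues)
    strands = (fwd, revcomp_codes(fwd))
    firsts, ctxs, nxts = [], [], []
    for codes in strands:
        kcodes, kvalid = window_codes(codes, k)
        tcodes, tvalid = window_codes(codes, k + 1)
        first = int(kcodes[np.argmax(kvalid)]) if kvalid.any() else -1
        t = tcodes[tvalid]
        firsts.append(first)
        ctxs.append(t >> 2)
        nxts.append(t & 3)
    return _EncodedRead(
        read_id=read.id,
        length=len(read.residues),
        first_kmer=(firsts[0], firsts[1]),
        contexts=(ctxs[0], ctxs[1]),
        next_bases=(nxts[0], nxts[1]),
    )


def _score_encoded(model: MarkovModel, er: _EncodedRead, both_strands: bool) -> float:
    best = -np.inf
    n_strands = 2 if both_strands else 1
    for s in range(n_strands):
        if er.first_kmer[s] < 0:
            continue
        score = model.initial_logprob[er.first_kmer[s]] + float(
            model.transition_logprob[er.contexts[s], er.next_bases[s]].sum()
        )
        best = max(best, score)
    return best


def score_read(model: MarkovModel, read: SequenceRecord, both_strands: bool = True) -> float | None:
    """Raw score (total log-likelihood, natural log) of a read, or None.

    Returns None when the read has no unambiguous (k+1)-mer (unscorable).
    The maximum of the forward and reverse-complement scores is returned
    unless ``both_strands`` is False.
    """
    er = _encode_read(read, model.k)
    if not er.scorable:
        return None
    return _score_encoded(model, er, both_strands)


def _score_partition(
    genome_paths: Sequence[str],
    encoded: Sequence[_EncodedRead],
    k: int,
    delta: float,
    both_strands: bool,
) -> list[ReadScore]:
    buf = _ModelBuffer(k, delta)
    out: list[ReadScore] = []
    for path in genome_paths:
        try:
            records = read_fasta(path)
        except OSError as exc:
            raise OSError(f"cannot read genome file {path}: {exc}") from exc
        if not records:
            raise ValueError(f"genome file {path} contains no sequences")
        buf.reset()
        buf.count(records)
        model = buf.finalize(_genome_id_from_path(path, records))
        for er in encoded:
            out.append(
                ReadScore(er.read_id, model.genome_id, _score_encoded(model, er, both_strands), er.length)
            )
    return out


def _genome_id_from_path(path: str, records: Sequence[SequenceRecord]) -> str:
    import os

    stem = os.path.basename(str(path))
    for suffix in (".fasta", ".fa", ".fna"):
        if stem.endswith(suffix):
            return stem[: -len(suffix)]
    return stem


def score_reads_against_genomes(
    reads: Sequence[SequenceRecord],
    genome_paths: Sequence[str],
    k: int,
    delta: float = 1.0,
    workers: int = 1,
    both_strands: bool = True,
) -> ScoreTable:
    """Score every read against every genome; one ReadScore per pair.

    Genomes are partitioned across workers; each worker streams its
    genomes against the shared read index through a single reusable
    model buffer. Results are keyed by (read_id, genome_id), so the
    table is bit-identical for any worker count.
    """
    _check_order(k)
    if not genome_paths:
        raise ValueError("at least one genome is required")
    encoded = [_encode_read(r, k) for r in reads]
    scorable = [er for er in encoded if er.scorable]
    unscorable = [er.read_id for er in encoded if not er.scorable]
    if unscorable:
        logger.warning("%d read(s) unscorable at order %d", len(unscorable), k)
    table = ScoreTable(unscorable=unscorable)
    if not scorable:
        warnings.warn("zero scorable reads", stacklevel=2)
        return table
    workers = max(1, min(workers, len(genome_paths)))
    parts = [list(genome_paths[i::workers]) for i in range(workers)]
    if workers == 1:
        chunks = [_score_partition(parts[0], scorable, k, delta, both_strands)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            chunks = list(
                pool.map(lambda p: _score_partition(p, scorable, k, delta, both_strands), parts)
            )
    per_read: dict[str, list[ReadScore]] = {er.read_id: [] for er in scorable}
    for chunk in chunks:
        for rs in chunk:
            per_read[rs.read_id].append(rs)
    for read_id, lst in per_read.items():
        lst.sort(key=lambda rs: (-rs.raw_score, rs.genome_id))
    table.scores = per_read
    return table


def top_n(table: ScoreTable, n: int) -> ScoreTable:
    """Keep the first min(n, #genomes) scores per read, order preserved."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return ScoreTable(
        scores={rid: lst[:n] for rid, lst in table.scores.items()},
        unscorable=list(table.unscorable),
    )
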