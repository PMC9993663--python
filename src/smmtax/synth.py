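"""Synthetic mosaic genomes, toy taxonomies and shotgun reads.

This generator is first-class: it emulates the mosaic compositional
structure of prokaryotic genomes (a host backbone plus compositionally
divergent island-like blocks) with parameterized order-m Markov sources,
and shotgun reads with uniform start/strand and i.i.d. substitution
errors. It makes every other module testable without any download.

It does *not* emulate indels, homopolymer artifacts, quality-dependent
error profiles, shared ancestry between taxa, or abundance skew.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._encode import encode
from .mjsd import CountProfile, mjsd
from .seqio import RANKS, Lineage, LineageMap, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SourceParams:
    """Order-``m_gen`` Markov source: rows of ``transition`` sum to 1."""

    m_gen: int
    transition: np.ndarray  # shape (4^m_gen, 4)
    label: str = "source"

    def __post_init__(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass
class MosaicSpec:
    """Ordered blocks of (source, length) composing one genome."""

    blocks: list[tuple[SourceParams, int]]
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        if any(length < 1 for _, length in self.blocks):
            raise ValueError("block lengths must be >= 1")


@dataclass
class ReadSimSpec:
    n_reads: int
    length: int | tuple[int, int] = 100  # fixed, or inclusive uniform range
    error_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def make_source(
    rng: np.random.Generator,
    gc_bias: float = 0.5,
    divergence_knob: float = 0.5,
    m_gen: int = 2,
    label: str = "source",
) -> SourceParams:
    """Draw a random order-``m_gen`` source.

    Each transition row is the mixture ``(1 - knob) * base + knob * d_w``
    with ``d_w`` a flat-Dirichlet draw and ``base`` the GC-biased
    single-nucleotide distribution. Knob 0 gives every source the same
    deterministic matrix; a larger knob gives independently drawn
    sources a larger expected pairwise MJSD.
    """
    if not 0 <= divergence_knob <= 1:
        raise ValueError("divergence_knob must be in [0, 1]")
    if not 0 < gc_bias < 1:
        raise ValueError("gc_bias must be in (0, 1)")
    base = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    n_ctx = 4**m_gen
    rows = rng.dirichlet(np.ones(4), size=n_ctx)
    transition = (1 - divergence_knob) * base + divergence_knob * rows
    transition /= transition.sum(axis=1, keepdims=True)
    return SourceParams(m_gen=m_gen, transition=transition, label=label)


def stationary_distribution(source: SourceParams) -> np.ndarray:
    """Stationary distribution over the 4^m contexts of the source chain."""
    m = source.m_gen
    n_ctx = 4**m
    # context w -> next context (w*4 + x) mod 4^m
    P = np.zeros((n_ctx, n_ctx))
    for w in range(n_ctx):
        for x in range(4):
            P[w, (w * 4 + x) % n_ctx] += source.transition[w, x]
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def stationary_gc(source: SourceParams) -> float:
    """Long-run GC fraction of the source chain."""
    pi = stationary_distribution(source)
    next_dist = pi @ source.transition
    return float(next_dist[1] + next_dist[2])


def _sample_chain(source: SourceParams, length: int, rng: np.random.Generator) -> np.ndarray:
    m = source.m_gen
    n_ctx = 4**m
    cdf = np.cumsum(source.transition, axis=1)
    out = np.empty(length, dtype=np.int64)
    ctx = int(rng.integers(n_ctx))
    u = rng.random(length)
    for i in range(length):
        x = int(np.searchsorted(cdf[ctx], u[i], side="right"))
        x = min(x, 3)
        out[i] = x
        ctx = (ctx * 4 + x) % n_ctx
    return out


def generate_mosaic_genome(
    spec: MosaicSpec, rng: np.random.Generator
) -> tuple[SequenceRecord, list[tuple[int, int, str]]]:
    """Sample a mosaic genome; returns (record, truth intervals).

    Truth intervals are 0-based half-open (start, end, source label).
    """
    parts: list[np.ndarray] = []
    truth: list[tuple[int, int, str]] = []
    pos = 0
    for source, length in spec.blocks:
        parts.append(_sample_chain(source, length, rng))
        truth.append((pos, pos + length, source.label))
        pos += length
    codes = np.concatenate(parts)
    residues = _BASES[codes].tobytes().decode("ascii")
    return SequenceRecord(id=spec.genome_id, residues=residues), truth


def pairwise_source_mjsd(a: SourceParams, b: SourceParams, n: int, rng: np.random.Generator, m: int = 0) -> float:
    """Order-m MJSD between length-n samples of two sources (diagnostic)."""
    from .mjsd import count_contexts

    sa = _sample_chain(a, n, rng)
    sb = _sample_chain(b, n, rng)
    return mjsd(count_contexts(sa, m), count_contexts(sb, m))


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    spec: ReadSimSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[tuple[str, str, int, str]]]:
    """Shotgun reads with substitution errors + per-read truth rows.

    The source genome is drawn with probability proportional to its
    length; the start is uniform over admissible positions and the
    strand uniform. Each base is substituted with probability
    ``error_rate`` to a uniformly chosen *different* base. Truth rows
    are (read_id, genome_id, start, strand).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    if isinstance(spec.length, tuple):
        lo_len, hi_len = spec.length
    else:
        lo_len = hi_len = spec.length
    lengths = np.array([len(g.residues) for g in genomes])
    if (lengths <= hi_len).any():
        raise ValueError("every genome must be longer than the maximum read length")
    weights = lengths / lengths.sum()
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    reads: list[SequenceRecord] = []
    truth: list[tuple[str, str, int, str]] = []
    encoded = [np.where(encode(g.residues) < 4, encode(g.residues), 0) for g in genomes]
    for i in range(spec.n_reads):
        gi = int(rng.choice(len(genomes), p=weights))
        read_len = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, lengths[gi] - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        codes = encoded[gi][start : start + read_len].copy()
        if strand == "-":
            codes = (3 - codes)[::-1].copy()
        if spec.error_rate > 0:
            hits = np.flatnonzero(rng.random(read_len) < spec.error_rate)
            for h in hits:
                codes[h] = (codes[h] + int(rng.integers(1, 4))) % 4
        read_id = f"read_{i}"
        reads.append(
            SequenceRecord(id=read_id, residues=_BASES[codes].tobytes().decode("ascii"))
        )
        truth.append((read_id, genomes[gi].id, start, strand))
    return reads, truth


def toy_taxonomy(genome_ids: Sequence[str], shared_ranks: int = 0) -> LineageMap:
    """Distinct lineages per genome; the top ``shared_ranks`` ranks shared."""
    lineages = {}
    for gid in genome_ids:
        names = tuple(
            f"{rank[:3].capitalize()}_shared" if i < shared_ranks else f"{rank[:3].capitalize()}_{gid}"
            for i, rank in enumerate(RANKS)
        )
        lineages[gid] = Lineage(names)
    return LineageMap(lineages)


def community(
    n_genomes: int,
    genome_length: int,
    divergence_knob: float = 0.8,
    seed: int = 0,
    m_gen: int = 2,
    gc_bias: float = 0.5,
) -> tuple[list[SequenceRecord], LineageMap]:
    """Convenience: n well-separated single-source genomes + toy taxonomy."""
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n_genomes):
        source = make_source(rng, gc_bias=gc_bias, divergence_knob=divergence_knob, m_gen=m_gen, label=f"src{i}")
        spec = MosaicSpec(blocks=[(source, genome_length)], genome_id=f"G{i}")
        rec, _ = generate_mosaic_genome(spec, rng)
        genomes.append(rec)
    return genomes, toy_taxonomy([g.id for g in genomes])
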