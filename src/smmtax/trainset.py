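"""Labeled calibration datasets from cluster-sampled genome fragments.

Fragments of random length (default 30-500 bp) are drawn from the
retained compositional clusters of each genome — clusters chosen with
probability proportional to their total length, fragments wholly inside
one member segment — then scored against the whole genome panel. The
top-N (default 50) hits per fragment become (raw score, read length,
correct?) rows, labeled per taxonomic rank against the fragment's
source lineage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mjsd import Cluster
from .seqio import RANKS, Lineage, LineageMap, SequenceRecord
from .smm import ScoreTable, score_reads_against_genomes, top_n

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Production defaults; tests scale ``reads_per_dataset`` down."""

    min_len: int = 30
    max_len: int = 500
    reads_per_dataset: int = 250_000
    n_datasets: int = 10
    top_n: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if min(self.n_datasets, self.top_n) < 1 or self.reads_per_dataset < 0:
            raise ValueError("counts must be >= 1 (reads_per_dataset >= 0)")


@dataclass(frozen=True)
class TrainingExample:
    raw_score: float
    read_length: int
    label: bool
    rank: str
    order: int


def sample_fragments(
    clusters_by_genome: Mapping[str, Sequence[Cluster]],
    genome_sequences: Mapping[str, str],
    lineage_map: LineageMap,
    config: TrainingConfig,
    rng: np.random.Generator,
    n_fragments: int | None = None,
) -> list[tuple[SequenceRecord, str]]:
    """Sample fragments from retained clusters; returns (fragment, source genome id).

    Per fragment: source genome uniform among eligible genomes, cluster
    proportional to its total length within the genome, member segment
    proportional to the number of admissible start positions, start
    uniform. Fragments never span a segment boundary; fragments with
    ambiguous bases are resampled (bounded retries). Genomes with no
    segment of at least ``min_len`` are skipped with a warning.
    """
    n_fragments = config.reads_per_dataset if n_fragments is None else n_fragments
    eligible: list[str] = []
    for gid, clusters in clusters_by_genome.items():
        if gid not in lineage_map:
            raise KeyError(f"genome {gid!r} missing from lineage map")
        if any(s.length >= config.min_len for c in clusters for s in c.members):
            eligible.append(gid)
        else:
            warnings.warn(f"genome {gid!r} has no segment >= {config.min_len} bp; skipped")
    if n_fragments == 0:
        return []
    if not eligible:
        raise ValueError("no genome has a retained cluster with a long-enough segment")

    out: list[tuple[SequenceRecord, str]] = []
    counter = 0
    while len(out) < n_fragments:
        gid = eligible[int(rng.integers(len(eligible)))]
        seq = genome_sequences[gid]
        clusters = clusters_by_genome[gid]
        weights = np.array([c.total_length for c in clusters], dtype=float)
        cluster = clusters[int(rng.choice(len(clusters), p=weights / weights.sum()))]
        for _ in range(20):  # bounded retries for length fit / ambiguity
            frag_len = int(rng.integers(config.min_len, config.max_len + 1))
            starts = np.array([max(0, s.length - frag_len + 1) for s in cluster.members], dtype=float)
            if starts.sum() == 0:
                continue
            seg = cluster.members[int(rng.choice(len(cluster.members), p=starts / starts.sum()))]
            start = seg.start + int(rng.integers(0, seg.length - frag_len + 1))
            residues = seq[start : start + frag_len].upper()
            if set(residues) <= set("ACGT"):
                out.append(
                    (SequenceRecord(id=f"frag_{counter}", residues=residues), gid)
                )
                counter += 1
                break
        else:
            logger.warning("fragment sampling from %s exhausted retries", gid)
    return out


def build_training_dataset(
    fragments: Sequence[tuple[SequenceRecord, str]],
    genome_paths: Sequence[str],
    lineage_map: LineageMap,
    rank: str,
    k: int,
    config: TrainingConfig = TrainingConfig(),
    workers: int = 1,
    score_table: ScoreTable | None = None,
) -> list[TrainingExample]:
    """Score fragments against the panel, keep top-N, label correctness.

    One example per retained (fragment, genome) pair; the label is True
    iff the scored genome and the fragment's source genome share the
    taxon name at ``rank``. Pairs where either lineage is unknown at the
    rank are excluded. A precomputed ``score_table`` may be supplied to
    label several ranks from one scoring pass.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    source_of = {frag.id: gid for frag, gid in fragments}
    if score_table is None:
        reads = [frag for frag, _ in fragments]
        score_table = score_reads_against_genomes(reads, genome_paths, k, workers=workers)
    table = top_n(score_table, config.top_n)
    examples: list[TrainingExample] = []
    for read_id, scores in table.scores.items():
        source_lineage = lineage_map[source_of[read_id]]
        if not source_lineage.known(rank):
            continue
        for rs in scores:
            hit_lineage = lineage_map[rs.genome_id]
            if not hit_lineage.known(rank):
                continue
            examples.append(
                TrainingExample(
                    raw_score=rs.raw_score,
                    read_length=rs.read_length,
                    label=hit_lineage.at(rank) == source_lineage.at(rank),
                    rank=rank,
                    order=k,
                )
            )
    return examples


def examples_to_frame(examples: Sequence[TrainingExample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "raw_score": [e.raw_score for e in examples],
            "read_length": [e.read_length for e in examples],
            "label": [e.label for e in examples],
            "rank": [e.rank for e in examples],
            "order": [e.order for e in examples],
        }
    )


def save_dataset(path, examples: Sequence[TrainingExample]) -> None:
    examples_to_frame(examples).to_csv(path, sep="\t", index=False)


def load_dataset(path) -> list[TrainingExample]:
    df = pd.read_csv(path, sep="\t")
    return [
        TrainingExample(r.raw_score, int(r.read_length), bool(r.label), r.rank, int(r.order))
        for r in df.itertuples()
    ]
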