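"""End-to-end read classification and hybrid merging.

Each read's best-scoring genome fixes a candidate lineage; the per-rank
calibration model turns the raw score and read length into a
probability, and a rank-level assignment is made iff that probability
clears the cutoff (default 0.25) and the lineage is known at the rank.

Hybrid mode merges with a first-pass exact-k-mer classifier's output:
reads the first pass classified are kept verbatim, reads it left
unclassified take the second-pass per-rank assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .calibrate import ScoreModel, predict_probability
from .seqio import RANKS, UNKNOWN, KrakenRecord, LineageMap, SequenceRecord
from .smm import ScoreTable, score_reads_against_genomes


@dataclass(frozen=True)
class ClassifierConfig:
    order: int = 10
    cutoff: float = 0.25
    top_n_report: int = 1
    workers: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")


@dataclass
class Assignment:
    """Per-read, per-rank taxon + probability + assigned flag."""

    read_id: str
    genome_id: str | None  # best-scoring genome; None if unscorable
    taxa: dict[str, str] = field(default_factory=dict)
    probabilities: dict[str, float] = field(default_factory=dict)
    assigned: dict[str, bool] = field(default_factory=dict)

    def at(self, rank: str) -> tuple[str, float, bool]:
        return self.taxa[rank], self.probabilities[rank], self.assigned[rank]


def classify_reads(
    reads: Sequence[SequenceRecord],
    genome_paths: Sequence[str],
    lineage_map: LineageMap,
    score_models: Mapping[str, ScoreModel],
    config: ClassifierConfig = ClassifierConfig(),
    score_table: ScoreTable | None = None,
) -> list[Assignment]:
    """Classify reads at every rank.

    ``score_models`` maps each of the six ranks to its calibration model
    at ``config.order``. The single top-scoring genome (ties to the
    lexicographically smaller genome id) supplies the candidate taxon at
    every rank; each rank is gated independently by its model's
    probability against the cutoff. Unscorable reads are reported
    unassigned at all ranks. A precomputed ``score_table`` may be
    passed to avoid re-scoring.
    """
    for rank in RANKS:
        if rank not in score_models:
            raise KeyError(f"missing score model for rank {rank!r}")
        if score_models[rank].order != config.order:
            raise ValueError(
                f"score model for {rank!r} has order {score_models[rank].order}, "
                f"classifier runs at order {config.order}"
            )
    if score_table is None:
        score_table = score_reads_against_genomes(
            reads, genome_paths, config.order, workers=config.workers
        )
    assignments: list[Assignment] = []
    for read in reads:
        if read.id in score_table.scores:
            best = score_table.best(read.id)
            lineage = lineage_map[best.genome_id]
            a = Assignment(read_id=read.id, genome_id=best.genome_id)
            for rank in RANKS:
                p = predict_probability(score_models[rank], best.raw_score, best.read_length)
                taxon = lineage.at(rank)
                a.taxa[rank] = taxon
                a.probabilities[rank] = p
                a.assigned[rank] = p >= config.cutoff and taxon != UNKNOWN
        else:  # unscorable
            a = Assignment(read_id=read.id, genome_id=None)
            for rank in RANKS:
                a.taxa[rank] = UNKNOWN
                a.probabilities[rank] = 0.0
                a.assigned[rank] = False
        assignments.append(a)
    return assignments


@dataclass(frozen=True)
class MergedRead:
    """One read of the hybrid output.

    First-pass reads carry the first-pass taxon verbatim with no
    probability; second-pass reads carry the full per-rank assignment.
    """

    read_id: str
    source: str  # "first_pass" | "second_pass"
    first_pass_taxon: str | None = None
    assignment: Assignment | None = None

    def at(self, rank: str) -> tuple[str, bool]:
        """(taxon, assigned) projection at one rank for evaluation."""
        if self.source == "first_pass":
            return self.first_pass_taxon, True
        taxon, _p, flag = self.assignment.at(rank)
        return taxon, flag


def hybrid_merge(
    first_pass: Sequence[KrakenRecord],
    second_pass: Sequence[Assignment],
) -> list[MergedRead]:
    """Merge first-pass classifications with second-pass assignments.

    Reads with first-pass status C keep their taxon untouched; status-U
    reads take the second-pass assignment. A second-pass assignment for
    a read the first pass already classified is an error (double
    classification). Output covers the union of read ids exactly once,
    first-pass file order first, then remaining second-pass reads in
    their order.
    """
    status = {rec.read_id: rec for rec in first_pass}
    second_ids = {a.read_id for a in second_pass}
    for a in second_pass:
        if a.read_id in status and status[a.read_id].status == "C":
            raise ValueError(
                f"read {a.read_id!r} classified by the first pass was re-classified"
            )
    by_id = {a.read_id: a for a in second_pass}
    merged: list[MergedRead] = []
    for rec in first_pass:
        if rec.status == "C":
            merged.append(
                MergedRead(rec.read_id, "first_pass", first_pass_taxon=rec.taxon)
            )
        elif rec.read_id in by_id:
            merged.append(
                MergedRead(rec.read_id, "second_pass", assignment=by_id[rec.read_id])
            )
    seen = {m.read_id for m in merged}
    for a in second_pass:
        if a.read_id not in seen:
            merged.append(MergedRead(a.read_id, "second_pass", assignment=a))
    return merged


def assignments_for_rank(
    assignments: Sequence[Assignment], rank: str
) -> dict[str, tuple[str | None, bool]]:
    """Project per-rank (taxon, assigned) pairs for the metrics tally."""
    return {a.read_id: (a.taxa[rank], a.assigned[rank]) for a in assignments}


def merged_for_rank(
    merged: Sequence[MergedRead], rank: str
) -> dict[str, tuple[str | None, bool]]:
    return {m.read_id: m.at(rank) for m in merged}
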