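"""Per-rank benchmark accounting: confusion counts, sensitivity, precision, F1.

Sensitivity at a rank is correct / total-with-known-truth (unclassified
reads count against it); precision is correct / (correct + incorrect)
(unclassified reads are excluded). Reads whose truth lineage is unknown
at the rank are excluded from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

from .seqio import Lineage


@dataclass(frozen=True)
class ConfusionCounts:
    """Three-way split of reads with known truth at one rank."""

    rank: str
    correct: int
    incorrect: int
    unclassified: int

    def __post_init__(self) -> None:
        if min(self.correct, self.incorrect, self.unclassified) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_known(self) -> int:
        return self.correct + self.incorrect + self.unclassified


@dataclass(frozen=True)
class RankMetrics:
    sensitivity: float | None
    precision: float | None
    f1: float | None


def tally(
    assignments: Mapping[str, tuple[str | None, bool]],
    truth: Mapping[str, Lineage],
    rank: str,
) -> ConfusionCounts:
    """Tally correct / incorrect / unclassified at one rank.

    ``assignments`` maps read_id -> (taxon, assigned flag); every
    assigned read must be present in ``truth``. Reads with unknown
    (sentinel) truth at the rank are excluded from all counts.
    """
    correct = incorrect = unclassified = 0
    for read_id, (taxon, assigned) in assignments.items():
        if read_id not in truth:
            raise KeyError(f"read {read_id!r} missing from truth")
        lineage = truth[read_id]
        if not lineage.known(rank):
            continue
        if not assigned:
            unclassified += 1
        elif taxon == lineage.at(rank):
            correct += 1
        else:
            incorrect += 1
    cc = ConfusionCounts(rank, correct, incorrect, unclassified)
    assert cc.correct + cc.incorrect + cc.unclassified == cc.total_known
    return cc


def compute_metrics(cc: ConfusionCounts) -> RankMetrics:
    """Sensitivity, precision and F1 from confusion counts.

    Undefined ratios (empty denominators) are reported as None, never
    silently as 0.
    """
    sens = cc.correct / cc.total_known if cc.total_known > 0 else None
    assigned = cc.correct + cc.incorrect
    prec = cc.correct / assigned if assigned > 0 else None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * sens * prec / (sens + prec)
    elif sens == prec == 0.0:
        f1 = 0.0
    else:
        f1 = None
    return RankMetrics(sens, prec, f1)


def format_percent(x: float) -> str:
    """Percentage with 2 decimals, round-half-even (banker's rounding)."""
    return str(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
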