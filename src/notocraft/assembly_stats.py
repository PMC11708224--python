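"""Contiguity, composition and completeness-summary arithmetic.

Standard assembly summary statistics: Nx/Lx, total/chromosome length
percentages, BUSCO count percentages, and raw read-set summaries.
Percentages are rounded half-up at the printed precision (2 decimals for
assembly percentages, 1 decimal for BUSCO), matching the convention of
published assembly tables.  Gap (N) bases count toward scaffold length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "AssemblySummary",
    "BuscoCounts",
    "ReadSetSummary",
    "round_half_up",
    "nx_lx",
    "summarize_assembly",
    "busco_percentages",
    "summarize_reads",
    "mean_read_length",
]


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places (table convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AssemblySummary:
    n_scaffolds: int
    total_length: int
    nx: dict[int, tuple[int, int]]
    largest: int
    n_chromosome_scaffolds: int
    chromosome_length: int
    pct_in_chromosomes: float


@dataclass
class BuscoCounts:
    """BUSCO classification counts; identities are enforced."""

    complete: int
    single: int
    duplicated: int
    fragmented: int
    missing: int
    total: int

    def validate(self) -> None:
        if min(self.complete, self.single, self.duplicated,
               self.fragmented, self.missing, self.total) < 0:
            raise ValueError("negative BUSCO count")
        if self.complete != self.single + self.duplicated:
            raise ValueError(
                f"complete ({self.complete}) != single + duplicated "
                f"({self.single} + {self.duplicated})"
            )
        if self.complete + self.fragmented + self.missing != self.total:
            raise ValueError(
                f"complete + fragmented + missing "
                f"({self.complete} + {self.fragmented} + {self.missing}) "
                f"!= total ({self.total})"
            )


@dataclass
class ReadSetSummary:
    count: int
    total: int
    mean: float
    n50: int
    n_over: dict[int, int] = field(default_factory=dict)


def nx_lx(lengths, x: float) -> tuple[int, int]:
    """(Nx, Lx): sort descending; Nx is the length at which the cumulative
    sum first reaches x% of the total, Lx its 1-based rank."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    if any(n <= 0 for n in lengths):
        raise ValueError("lengths must be positive")
    threshold = x / 100 * sum(lengths)
    cumulative = 0
    for rank, n in enumerate(lengths, start=1):
        cumulative += n
        if cumulative >= threshold:
            return n, rank
    raise AssertionError("unreachable")  # cumulative == total >= threshold


def summarize_assembly(scaffolds, chromosome_ids, nx_levels=(50, 90)) -> AssemblySummary:
    """Summarize scaffold lengths plus the designated chromosome subset.

    ``scaffolds`` maps scaffold id -> length (or is an iterable of
    records with ``id`` and a length).  Chromosome-level scaffolds are an
    explicit id list, not a length threshold.
    """
    if isinstance(scaffolds, dict):
        lengths = dict(scaffolds)
    else:
        lengths = {rec.id: len(rec.sequence) for rec in scaffolds}
    unknown = set(chromosome_ids) - set(lengths)
    if unknown:
        raise ValueError(f"unknown chromosome ids: {sorted(unknown)}")
    total = sum(lengths.values())
    chrom_total = sum(lengths[c] for c in chromosome_ids)
    return AssemblySummary(
        n_scaffolds=len(lengths),
        total_length=total,
        nx={x: nx_lx(list(lengths.values()), x) for x in nx_levels},
        largest=max(lengths.values()),
        n_chromosome_scaffolds=len(set(chromosome_ids)),
        chromosome_length=chrom_total,
        pct_in_chromosomes=round_half_up(100 * chrom_total / total, 2),
    )


def busco_percentages(counts: BuscoCounts) -> dict[str, float]:
    """Percentages of total for each BUSCO class, 1 decimal, half-up."""
    counts.validate()
    if counts.total == 0:
        raise ValueError("total BUSCO count is zero")
    return {
        name: round_half_up(100 * getattr(counts, name) / counts.total, 1)
        for name in ("complete", "single", "duplicated", "fragmented", "missing")
    }


def mean_read_length(total_bp: float, count: int) -> float:
    """Mean read length (2 decimals) from a total-bp / read-count pair."""
    if count <= 0:
        raise ValueError("count must be positive")
    return round_half_up(total_bp / count, 2)


def summarize_reads(lengths, thresholds=(20_000, 50_000)) -> ReadSetSummary:
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty read set")
    total = sum(lengths)
    n50, _ = nx_lx(lengths, 50)
    return ReadSetSummary(
        count=len(lengths),
        total=total,
        mean=mean_read_length(total, len(lengths)),
        n50=n50,
        n_over={t: sum(1 for n in lengths if n > t) for t in thresholds},
    )
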