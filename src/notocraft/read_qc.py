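"""Long-read subsampling and overlap-based scrubbing.

Two raw-data preparation strategies for uncorrected long reads (PacBio
CLR-style):

1. **Subsampling** — select reads within a length window, in input order,
   until a total-basepair budget is met.
2. **Scrubbing** — from filtered all-vs-all overlaps, compute a per-base
   coverage profile for each read and remove reads that are chimeric
   (an interior coverage collapse, the signature of two unrelated
   fragments joined by a library artifact) or that carry large
   low-coverage regions (default: coverage <= 3x over >= 40% of the
   read).

The all-vs-all alignment itself is out of scope (an aligner's job); the
input is a PAF-like overlap table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Overlap",
    "ScrubParams",
    "SampleParams",
    "ReadStatus",
    "sample_reads",
    "filter_overlaps",
    "coverage_profile",
    "scrub_reads",
]


@dataclass
class Overlap:
    """One read-vs-read alignment record (0-based half-open spans)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    tname: str
    tlen: int
    tstart: int
    tend: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query span on {self.qname}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target span on {self.tname}")


@dataclass
class ScrubParams:
    """Thresholds for low-coverage/chimera removal."""

    min_coverage: int = 3
    min_low_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if not (0 < self.min_low_fraction <= 1):
            raise ValueError("min_low_fraction must be in (0, 1]")


@dataclass
class SampleParams:
    """Length window and total-basepair budget for read subsampling."""

    min_len: int = 10_000
    max_len: int = 40_000
    budget: int = 70_000_000_000

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.budget < 0:
            raise ValueError("budget must be >= 0")


class ReadStatus(str, Enum):
    KEPT = "kept"
    REMOVED_LOW_COVERAGE = "removed_low_coverage"
    REMOVED_CHIMERIC = "removed_chimeric"


def sample_reads(reads, params: SampleParams, shuffle_seed: int | None = None):
    """Select reads within [min_len, max_len] until the budget is met.

    Reads are taken in input order (deterministic); pass ``shuffle_seed``
    to randomize the order first.  Selection stops with the first read
    whose inclusion brings the cumulative length to >= budget (that read
    is included).  A warning is issued if the supply runs out first.
    """
    order = list(reads)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        order = [order[i] for i in rng.permutation(len(order))]
    selected = []
    total = 0
    if params.budget == 0:
        return selected
    for read in order:
        n = len(read.sequence)
        if not (params.min_len <= n <= params.max_len):
            continue
        selected.append(read)
        total += n
        if total >= params.budget:
            break
    if total < params.budget:
        warnings.warn(
            f"budget unmet: selected {total} bp of {params.budget} requested",
            stacklevel=2,
        )
    return selected


def _is_internal_match(ov: Overlap, end_tol: int = 50) -> bool:
    """True when one read is fully contained inside the other's span.

    "Fully contained" means the contained read aligns over (within
    ``end_tol`` of) its whole length while neither alignment boundary on
    the containing read comes within ``end_tol`` of that read's ends —
    i.e. the match is internal to the container, not a dovetail.
    """
    q_full = ov.qstart <= end_tol and (ov.qlen - ov.qend) <= end_tol
    t_internal = ov.tstart > end_tol and (ov.tlen - ov.tend) > end_tol
    if q_full and t_internal:
        return True
    t_full = ov.tstart <= end_tol and (ov.tlen - ov.tend) <= end_tol
    q_internal = ov.qstart > end_tol and (ov.qlen - ov.qend) > end_tol
    return t_full and q_internal


def filter_overlaps(overlaps, min_overlap_len: int = 2_000, end_tol: int = 50):
    """Drop short overlaps and internal matches.

    An overlap is dropped when its aligned query span is shorter than
    ``min_overlap_len`` bp, or when it is an internal match (one read's
    full length contained inside the other — see
    :func:`_is_internal_match`).  Idempotent.
    """
    kept = []
    for ov in overlaps:
        if ov.qend - ov.qstart < min_overlap_len:
            continue
        if _is_internal_match(ov, end_tol=end_tol):
            continue
        kept.append(ov)
    return kept


def coverage_profile(read_length: int, spans) -> np.ndarray:
    """Per-base coverage from (start, end) spans on one read.

    Each span contributes 1 to every covered position; duplicated spans
    count twice.  Spans outside [0, read_length] raise.
    """
    delta = np.zeros(read_length + 1, dtype=np.int64)
    for start, end in spans:
        if not (0 <= start < end <= read_length):
            raise ValueError(f"span [{start}, {end}) outside read of length {read_length}")
        delta[start] += 1
        delta[end] -= 1
    return np.cumsum(delta[:-1])


def _spans_on_read(name: str, overlaps):
    """All aligned spans touching ``name``, in both query and target roles."""
    for ov in overlaps:
        if ov.qname == name:
            yield (ov.qstart, ov.qend)
        if ov.tname == name:
            yield (ov.tstart, ov.tend)


def scrub_reads(reads, overlaps, params: ScrubParams | None = None) -> dict[str, ReadStatus]:
    """Classify each read as kept / removed_low_coverage / removed_chimeric.

    Coverage is computed from overlaps in both query and target roles.
    A read is *chimeric* when some maximal run of positions with coverage
    <= ``min_coverage`` is strictly interior — flanked on both sides by
    runs above the threshold.  A read is *low-coverage* when such
    positions make up >= ``min_low_fraction`` of its length.  Chimeric
    takes precedence in reporting.

    ``overlaps`` should already have passed :func:`filter_overlaps`.
    """
    if params is None:
        params = ScrubParams()
    known = {r.id for r in reads}
    by_read: dict[str, list[tuple[int, int]]] = {r.id: [] for r in reads}
    for ov in overlaps:
        for name, span in ((ov.qname, (ov.qstart, ov.qend)),
                           (ov.tname, (ov.tstart, ov.tend))):
            if name not in known:
                raise ValueError(f"overlap references unknown read {name}")
            by_read[name].append(span)

    result: dict[str, ReadStatus] = {}
    for read in reads:
        n = len(read.sequence)
        cov = coverage_profile(n, by_read[read.id])
        low = cov <= params.min_coverage
        n_low = int(low.sum())
        chimeric = False
        if n_low:
            # maximal low runs; interior <=> flanked by high coverage on both sides
            boundaries = np.flatnonzero(np.diff(low.astype(np.int8)))
            starts = [0] + (boundaries + 1).tolist()
            for i, s in enumerate(starts):
                e = starts[i + 1] if i + 1 < len(starts) else n
                if low[s] and s > 0 and e < n:
                    chimeric = True
                    break
        if chimeric:
            result[read.id] = ReadStatus.REMOVED_CHIMERIC
        elif n_low >= params.min_low_fraction * n:
            result[read.id] = ReadStatus.REMOVED_LOW_COVERAGE
        else:
            result[read.id] = ReadStatus.KEPT
    return result
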