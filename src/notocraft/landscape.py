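"""Windowed density tracks, Kimura repeat landscapes, k-mer klump
detection and CDS integrity checks.

The repeat landscape summarizes, per repeat class, how much of the
genome is covered by repeat copies at each percent of Kimura 2-parameter
divergence from the family consensus — divergence being a proxy for
insertion age, so mass at low divergence indicates a recent expansion.

Plain K2P is used (no CpG adjustment): over ungapped, unambiguous
aligned columns, with transition proportion P and transversion
proportion Q,

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DensityParams",
    "DivergenceBin",
    "KlumpParams",
    "Klump",
    "GeneIntegrityReport",
    "LandscapeResult",
    "SaturationError",
    "windowed_density",
    "kimura_k2p",
    "repeat_landscape",
    "find_klumps",
    "check_gene_integrity",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class SaturationError(ValueError):
    """Raised when the K2P distance is undefined (log argument <= 0)."""


@dataclass
class DensityParams:
    """Sliding-window parameters: a new ``window`` every ``step`` bp."""

    window: int = 250_000
    step: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")


@dataclass
class DivergenceBin:
    """Genome coverage of one repeat class at one 1%-wide divergence bin."""

    bin_lower_pct: int
    class_label: str
    bp_covered: int
    genome_fraction: float


@dataclass
class LandscapeResult:
    bins: list[DivergenceBin]
    n_saturated_skipped: int = 0


@dataclass
class KlumpParams:
    ksize: int = 17
    min_kmers: int = 20
    range: int = 1_000

    def __post_init__(self) -> None:
        if self.ksize < 3:
            raise ValueError("ksize must be >= 3")
        if self.min_kmers < 1 or self.range < 1:
            raise ValueError("min_kmers and range must be >= 1")


@dataclass
class Klump:
    query_id: str
    start: int
    end: int
    kmer_count: int


@dataclass
class GeneIntegrityReport:
    gene_id: str
    status: str  # intact | premature_stop | frameshift | incomplete
    details: dict = field(default_factory=dict)


def windowed_density(features, chrom_lengths: dict[str, int],
                     params: DensityParams | None = None):
    """Tally features in sliding windows along each chromosome.

    Windows start at 0 and advance by ``step``; the last windows are
    truncated at the chromosome end, and every window whose start is
    below the chromosome length is emitted.  A feature is counted in a
    window iff its midpoint lies in [win_start, win_end) — so for
    non-overlapping windows (step == window) counts sum to the number of
    features.  Returns rows (chrom, win_start, win_end, count).
    """
    if params is None:
        params = DensityParams()
    by_chrom: dict[str, list[float]] = {c: [] for c in chrom_lengths}
    for feat in features:
        if feat.seqid not in chrom_lengths:
            raise ValueError(f"feature on unknown chromosome {feat.seqid}")
        if feat.end > chrom_lengths[feat.seqid]:
            raise ValueError(
                f"feature [{feat.start}, {feat.end}) beyond end of {feat.seqid}"
            )
        by_chrom[feat.seqid].append(feat.midpoint)
    rows = []
    for chrom, length in chrom_lengths.items():
        midpoints = sorted(by_chrom[chrom])
        start = 0
        while start < length:
            end = min(start + params.window, length)
            count = sum(1 for m in midpoints if start <= m < end)
            rows.append((chrom, start, end, count))
            start += params.step
    return rows


def kimura_k2p(aligned_copy: str, aligned_consensus: str) -> tuple[float, float, float]:
    """Kimura 2-parameter (P, Q, K) from one aligned pair.

    Only ungapped columns where both bases are in {A,C,G,T} enter the
    P/Q denominators (gaps and ambiguity codes are excluded).  Raises
    :class:`SaturationError` when the distance is undefined.
    """
    if len(aligned_copy) != len(aligned_consensus):
        raise ValueError("aligned strings differ in length")
    n = transitions = transversions = 0
    for a, b in zip(aligned_copy.upper(), aligned_consensus.upper()):
        if a not in _BASES or b not in _BASES:
            continue
        n += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("no ungapped unambiguous columns")
    P = transitions / n
    Q = transversions / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair: P={P:.3f}, Q={Q:.3f}")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, K


def _ungapped_aligned_bp(aligned_copy: str, aligned_consensus: str) -> int:
    return sum(
        1 for a, b in zip(aligned_copy.upper(), aligned_consensus.upper())
        if a != "-" and b != "-"
    )


def repeat_landscape(pairs, genome_size: int) -> LandscapeResult:
    """Bin repeat copies by Kimura divergence, stacked per class.

    ``pairs`` yields (class_label, aligned_copy, aligned_consensus)
    triples (or objects with those attributes).  Each copy contributes
    its ungapped aligned bp to bin floor(100*K) of its class;
    ``genome_fraction`` is bp over ``genome_size``.  Saturated pairs are
    skipped and counted.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    acc: dict[tuple[int, str], int] = {}
    skipped = 0
    for pair in pairs:
        if isinstance(pair, tuple):
            label, copy, consensus = pair
        else:
            label, copy, consensus = pair.class_label, pair.aligned_copy, pair.aligned_consensus
        try:
            _, _, K = kimura_k2p(copy, consensus)
        except SaturationError:
            skipped += 1
            continue
        key = (int(math.floor(100 * K)), label)
        acc[key] = acc.get(key, 0) + _ungapped_aligned_bp(copy, consensus)
    bins = [
        DivergenceBin(
            bin_lower_pct=b,
            class_label=label,
            bp_covered=bp,
            genome_fraction=bp / genome_size,
        )
        for (b, label), bp in sorted(acc.items())
    ]
    return LandscapeResult(bins=bins, n_saturated_skipped=skipped)


def _canonical_kmers(seq: str, k: int):
    """Yield (position, canonical k-mer) over ACGT-only k-mers."""
    seq = seq.upper()
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) - _BASES:
            continue
        rkmer = rc[n - k - i:n - i]
        yield i, min(kmer, rkmer)


def find_klumps(query_seqs, reference_seq, params: KlumpParams | None = None) -> list[Klump]:
    """Locate clusters of reference k-mer matches ("klumps") in queries.

    K-mers are strand-collapsed (canonical form), so both strands of the
    query are effectively checked and the output is invariant under
    reverse-complementing the reference.  Consecutive match positions on
    a query within ``range`` bp (start-to-start) group into one klump;
    klumps with fewer than ``min_kmers`` matches are discarded.  The
    klump span runs from the first match start to the last match start
    plus ``ksize``.
    """
    if params is None:
        params = KlumpParams()
    ref = reference_seq.sequence if hasattr(reference_seq, "sequence") else reference_seq
    if len(ref) < params.ksize:
        raise ValueError("reference shorter than ksize")
    ref_kmers = {kmer for _, kmer in _canonical_kmers(ref, params.ksize)}
    klumps: list[Klump] = []
    for rec in query_seqs:
        matches = [
            pos for pos, kmer in _canonical_kmers(rec.sequence, params.ksize)
            if kmer in ref_kmers
        ]
        if not matches:
            continue
        group = [matches[0]]
        for pos in matches[1:] + [None]:
            if pos is not None and pos - group[-1] <= params.range:
                group.append(pos)
            else:
                if len(group) >= params.min_kmers:
                    klumps.append(
                        Klump(rec.id, group[0], group[-1] + params.ksize, len(group))
                    )
                if pos is not None:
                    group = [pos]
    return klumps


def check_gene_integrity(cds_seq: str, gene_id: str = "") -> GeneIntegrityReport:
    """Translate a CDS and flag pseudogenization signatures.

    Status: ``frameshift`` when length % 3 != 0; else ``premature_stop``
    when a stop codon occurs before the final codon; else ``intact`` when
    the final codon is a stop, ``incomplete`` otherwise.  A missing ATG
    start is reported in details without changing the status.
    """
    seq = cds_seq.upper()
    if set(seq) - (_BASES | {"N"}):
        raise ValueError("non-ACGTN characters in CDS")
    details: dict = {"length_mod_3": len(seq) % 3}
    if not seq.startswith("ATG"):
        details["missing_start_codon"] = True
    if len(seq) % 3 != 0:
        return GeneIntegrityReport(gene_id, "frameshift", details)
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons[:-1]):
        if codon in _STOP_CODONS:
            details["first_stop_codon"] = idx + 1  # 1-based codon index
            return GeneIntegrityReport(gene_id, "premature_stop", details)
    if codons and codons[-1] in _STOP_CODONS:
        return GeneIntegrityReport(gene_id, "intact", details)
    details["missing_terminal_stop"] = True
    return GeneIntegrityReport(gene_id, "incomplete", details)
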